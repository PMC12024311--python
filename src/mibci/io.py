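"""Acquisition CSV reader/writer.

The interchange format is the acquisition software's table, bit-exact:
header ``timestamp,ch1_delta,...,ch8_gamma,label`` (channel-major, five bands
per channel), timestamps in seconds with six decimals, lower-case label
strings, UTF-8, LF line endings, '.' decimal separator.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .labels import EpochLabel
from .synth import BandPowerTable, feature_column_names


def write_acquisition_csv(table: BandPowerTable, path: str | Path) -> Path:
    p = Path(path)
    cols = table.feature_columns
    with open(p, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("timestamp," + ",".join(cols) + ",label\n")
        feats = table.features
        ts = table.timestamps
        labs = table.frame["label"].tolist()
        for i in range(len(ts)):
            vals = ",".join(repr(float(v)) for v in feats[i])
            fh.write(f"{ts[i]:.6f},{vals},{labs[i]}\n")
    return p


def read_acquisition_csv(path: str | Path, n_channels: int = 8) -> BandPowerTable:
    """Parse and validate an acquisition CSV.

    Schema violations (wrong column set) raise :class:`SchemaError` naming the
    missing/extra columns; malformed rows raise with their line numbers; a
    file whose rows all carry one label loads but emits a warning.
    """
    p = Path(path)
    if not p.exists():
        raise SchemaError(f"no such file: {p}")
    df = pd.read_csv(p, dtype=str, keep_default_na=False)
    expected = ["timestamp"] + feature_column_names(n_channels) + ["label"]
    got = list(df.columns)
    if got != expected:
        missing = sorted(set(expected) - set(got))
        extra = sorted(set(got) - set(expected))
        raise SchemaError(
            f"{p.name}: header does not match the acquisition schema; "
            f"missing columns: {missing or 'none'}; unexpected columns: {extra or 'none'}"
        )
    bad_lines: list[str] = []
    numeric = {}
    for col in expected[:-1]:
        raw = df[col].to_numpy()
        out = np.empty(len(raw))
        n_bad = 0
        for i, s in enumerate(raw):
            try:
                out[i] = float(s)  # exact round-trip of repr()ed doubles
            except (TypeError, ValueError):
                out[i] = np.nan
                n_bad += 1
                if n_bad <= 5:
                    bad_lines.append(f"line {i + 2}: non-numeric {col}={s!r}")
        numeric[col] = out
    labels = []
    for i, s in enumerate(df["label"]):
        try:
            labels.append(EpochLabel.from_string(s).value)
        except ValueError:
            bad_lines.append(f"line {i + 2}: {s!r} is not a valid label")
            labels.append(None)
    if bad_lines:
        shown = "; ".join(bad_lines[:10])
        raise SchemaError(f"{p.name}: {len(bad_lines)} malformed value(s): {shown}")
    frame = pd.DataFrame({**numeric, "label": labels})
    if (frame[expected[1:-1]].to_numpy() < 0).any():
        neg = int((frame[expected[1:-1]].to_numpy() < 0).sum())
        raise SchemaError(f"{p.name}: {neg} negative band-power value(s)")
    if frame["label"].nunique() == 1:
        warnings.warn(
            f"{p.name}: every row carries the single label "
            f"{frame['label'].iloc[0]!r}; classifiers cannot be trained on it",
            stacklevel=2,
        )
    return BandPowerTable(frame)
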