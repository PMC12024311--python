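"""On-disk model bundle: a fitted classifier plus its feature recipe.

A bundle is a directory holding the classifier weights, the wavelet
specification and statistic order of the feature stage, the normalization
parameters, the class-label order and the windowing geometry — everything the
streaming engine needs to reproduce training-time features on live rows.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .features import DEFAULT_STATS
from .models import FittedModel, ModelKind, features_for_kind
from .wavelets import WaveletSpec

_FORMAT_VERSION = 1


@dataclass
class ModelBundle:
    model: FittedModel
    wavelet_spec: WaveletSpec
    stats: tuple[str, ...]
    column_names: list[str]
    window_rows: int
    hop_rows: int
    n_seq_steps: int = 16

    def featurize_window(self, window: np.ndarray) -> np.ndarray:
        """Training-time feature vector for one [window_rows, n_columns] window."""
        w = np.asarray(window, dtype=float)
        if w.shape != (self.window_rows, len(self.column_names)):
            raise ConfigurationError(
                f"window shape {w.shape} does not match bundle geometry "
                f"({self.window_rows}, {len(self.column_names)})"
            )
        from .features import WindowDataset

        ds = WindowDataset(
            windows=w[None, :, :],
            labels=np.array([None], dtype=object),
            end_times=np.zeros(1),
            column_names=self.column_names,
        )
        return features_for_kind(
            self.model.kind, ds, self.wavelet_spec, n_seq_steps=self.n_seq_steps
        )[0]

    def save(self, directory: str | Path) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.model.save(d / "model")
        meta = {
            "format_version": _FORMAT_VERSION,
            "wavelet": self.wavelet_spec.wavelet_name,
            "level": self.wavelet_spec.level,
            "stats": list(self.stats),
            "column_names": self.column_names,
            "window_rows": self.window_rows,
            "hop_rows": self.hop_rows,
            "n_seq_steps": self.n_seq_steps,
        }
        (d / "bundle.json").write_text(json.dumps(meta, indent=2))
        return d

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        d = Path(directory)
        meta_path = d / "bundle.json"
        if not meta_path.exists():
            raise ConfigurationError(f"{d} is not a model bundle (no bundle.json)")
        meta = json.loads(meta_path.read_text())
        if meta.get("format_version") != _FORMAT_VERSION:
            raise ConfigurationError(
                f"unsupported bundle format version {meta.get('format_version')}"
            )
        return cls(
            model=FittedModel.load(d / "model"),
            wavelet_spec=WaveletSpec(meta["wavelet"], meta["level"]),
            stats=tuple(meta["stats"]),
            column_names=list(meta["column_names"]),
            window_rows=meta["window_rows"],
            hop_rows=meta["hop_rows"],
            n_seq_steps=meta.get("n_seq_steps", 16),
        )
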