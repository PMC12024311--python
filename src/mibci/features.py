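"""Fixed-length feature vectors from windowed multichannel series.

Each channel of a window is decomposed with the multilevel DWT; each of the
``level + 1`` coefficient arrays is summarized by four statistics (mean,
standard deviation, energy, max absolute value), giving a vector of length
``n_channels * (level + 1) * n_stats`` regardless of window length. Layout is
channel-major, then coefficient array (``cA_n, cD_n, ..., cD_1``), then
statistic — recorded in :class:`FeatureLayout` so saved models can be reused
on live streams.

The window source is either the 40-column band-power table (the pipeline
default, matching the acquisition CSV) or raw channel amplitudes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from .errors import ConfigurationError
from .labels import CLASS_ORDER, EpochLabel
from .synth import BandPowerTable
from .wavelets import _BOUNDARY_MODE, WaveletSpec

#: default summary statistics, in layout order
DEFAULT_STATS: tuple[str, ...] = ("mean", "std", "energy", "maxabs")

_STAT_FUNCS = {
    "mean": lambda a: a.mean(axis=0),
    "std": lambda a: a.std(axis=0),
    "energy": lambda a: (a**2).sum(axis=0),
    "maxabs": lambda a: np.abs(a).max(axis=0),
}


@dataclass(frozen=True)
class FeatureLayout:
    """Index map of a feature vector: (channel, coefficient array, statistic)."""

    channel_names: tuple[str, ...]
    level: int
    stats: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return len(self.channel_names) * (self.level + 1) * len(self.stats)

    def names(self) -> list[str]:
        arrays = [f"cA{self.level}"] + [f"cD{k}" for k in range(self.level, 0, -1)]
        return [
            f"{ch}__{arr}__{st}"
            for ch in self.channel_names
            for arr in arrays
            for st in self.stats
        ]


def extract_features(
    window: np.ndarray,
    spec: WaveletSpec,
    stats: tuple[str, ...] = DEFAULT_STATS,
) -> np.ndarray:
    """Feature vector for one ``[n_samples, n_channels]`` window."""
    w = np.asarray(window, dtype=float)
    if w.ndim != 2:
        raise ConfigurationError(f"window must be 2-D [n_samples, n_channels], got {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ConfigurationError("window contains non-finite samples")
    unknown = [s for s in stats if s not in _STAT_FUNCS]
    if unknown:
        raise ConfigurationError(f"unknown statistics {unknown}; known: {list(_STAT_FUNCS)}")
    spec.validate_for_length(w.shape[0])
    coeffs = pywt.wavedec(w, spec.wavelet_name, mode=_BOUNDARY_MODE, level=spec.level, axis=0)
    # [n_channels, n_arrays, n_stats] -> ravel, channel-major
    per_array = np.stack(
        [np.stack([_STAT_FUNCS[s](np.asarray(c)) for s in stats], axis=-1) for c in coeffs],
        axis=1,
    )
    return per_array.reshape(-1)


def extract_feature_matrix(
    windows: np.ndarray, spec: WaveletSpec, stats: tuple[str, ...] = DEFAULT_STATS
) -> np.ndarray:
    """Vectorized :func:`extract_features` over ``[n_windows, n_samples, n_channels]``."""
    w = np.asarray(windows, dtype=float)
    if w.ndim != 3:
        raise ConfigurationError(f"expected 3-D window stack, got {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ConfigurationError("windows contain non-finite samples")
    spec.validate_for_length(w.shape[1])
    coeffs = pywt.wavedec(w, spec.wavelet_name, mode=_BOUNDARY_MODE, level=spec.level, axis=1)
    per_array = np.stack(
        [np.stack([_STAT_FUNCS[s](np.moveaxis(np.asarray(c), 1, 0)) for s in stats], axis=-1)
         for c in coeffs],
        axis=2,
    )  # [n_windows, n_channels, n_arrays, n_stats]
    return per_array.reshape(w.shape[0], -1)


@dataclass(frozen=True)
class WPTSearchSpace:
    """Wavelet/level grid explored by the randomized feature search."""

    wavelets: tuple[str, ...] = ("db4", "coif1", "sym5")
    levels: tuple[int, ...] = (3, 4, 5)

    def __post_init__(self) -> None:
        if not self.wavelets or not self.levels:
            raise ConfigurationError("search space must contain at least one wavelet and one level")

    def validate_for_length(self, window_length: int) -> None:
        for w in self.wavelets:
            for l in self.levels:
                WaveletSpec(w, l).validate_for_length(window_length)

    def cells(self) -> list[WaveletSpec]:
        return [WaveletSpec(w, l) for w in self.wavelets for l in self.levels]


def sample_wpt_hyperparams(space: WPTSearchSpace, seed: int) -> WaveletSpec:
    """Uniform draw over wavelets x levels; deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    w = space.wavelets[int(rng.integers(len(space.wavelets)))]
    l = space.levels[int(rng.integers(len(space.levels)))]
    return WaveletSpec(w, l)


# ---------------------------------------------------------------------------
# windowing of band-power tables


@dataclass
class WindowDataset:
    """Windowed views of one or more band-power tables.

    windows : [n_windows, window_rows, n_columns] raw band-power rows.
    labels : majority label per window (ties toward rest).
    end_times : timestamp of each window's last row (no lookahead past it).
    """

    windows: np.ndarray
    labels: np.ndarray
    end_times: np.ndarray
    column_names: list[str]

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    def mean_band_powers(self) -> np.ndarray:
        """Per-window mean of each band-power column — the no-wavelet features."""
        return self.windows.mean(axis=1)

    def sequences(self, n_steps: int = 16) -> np.ndarray:
        """Down-sampled ``[n_windows, n_steps, n_columns]`` sequences for recurrent models."""
        idx = np.linspace(0, self.windows.shape[1] - 1, n_steps).round().astype(int)
        return self.windows[:, idx, :]

    def wavelet_features(
        self, spec: WaveletSpec, stats: tuple[str, ...] = DEFAULT_STATS
    ) -> np.ndarray:
        return extract_feature_matrix(self.windows, spec, stats)


def majority_label(labels: np.ndarray) -> EpochLabel:
    """Most frequent label; ties resolved toward rest, then class order."""
    counts = np.array([np.sum(labels == lab) for lab in CLASS_ORDER], dtype=float)
    counts[CLASS_ORDER.index(EpochLabel.REST)] += 0.5
    return CLASS_ORDER[int(np.argmax(counts))]


def make_windows(
    tables: BandPowerTable | list[BandPowerTable],
    window_rows: int = 384,
    hop_rows: int = 64,
) -> WindowDataset:
    """Slice band-power tables into overlapping windows.

    Defaults (384-row windows, 64-row hop) correspond to ~3 s windows every
    ~0.5 s at the generator's 125 rows/s cadence; 384 is divisible by 2**5 so
    every wavelet in the default search space is admissible at level 5.
    Windows never span table (subject) boundaries.
    """
    if isinstance(tables, BandPowerTable):
        tables = [tables]
    if window_rows < 1 or hop_rows < 1:
        raise ConfigurationError("window_rows and hop_rows must be >= 1")
    cols = tables[0].feature_columns
    wins, labs, ends = [], [], []
    for t in tables:
        if t.feature_columns != cols:
            raise ConfigurationError("all tables must share the same feature columns")
        X = t.features
        ts = t.timestamps
        y = t.labels
        for start in range(0, len(X) - window_rows + 1, hop_rows):
            sl = slice(start, start + window_rows)
            wins.append(X[sl])
            labs.append(majority_label(y[sl]))
            ends.append(ts[start + window_rows - 1])
    if not wins:
        raise ConfigurationError(
            f"no table has {window_rows} rows; windows would be empty"
        )
    return WindowDataset(
        windows=np.stack(wins),
        labels=np.array(labs, dtype=object),
        end_times=np.array(ends),
        column_names=cols,
    )


# ---------------------------------------------------------------------------
# normalization


@dataclass
class Zscaler:
    """Per-feature z-score; parameters fit on training folds only."""

    mean_: np.ndarray | None = field(default=None)
    scale_: np.ndarray | None = field(default=None)

    def fit(self, X: np.ndarray) -> "Zscaler":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0  # constant features pass through centred
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ConfigurationError("Zscaler used before fit")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Zscaler":
        return cls(mean_=np.asarray(d["mean"], dtype=float), scale_=np.asarray(d["scale"], dtype=float))


def save_feature_sidecar(
    path, spec: WaveletSpec, stats: tuple[str, ...], scaler: Zscaler | None, layout: FeatureLayout
) -> None:
    """JSON sidecar recording how a persisted feature matrix was produced."""
    doc = {
        "wavelet": spec.wavelet_name,
        "level": spec.level,
        "stats": list(stats),
        "channels": list(layout.channel_names),
        "normalization": scaler.to_dict() if scaler is not None else None,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)


def save_feature_matrix(path, X: np.ndarray, labels: np.ndarray, layout: FeatureLayout) -> None:
    df = pd.DataFrame(X, columns=layout.names())
    df["label"] = [str(l) for l in labels]
    df.to_csv(path, index=False)
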