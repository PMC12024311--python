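"""Synthetic EEG sessions with controllable ERD/ERS ground truth.

The generator emulates an 8-channel motor-imagery acquisition session: a 1/f
("pink") background per channel, plus band-limited oscillations (alpha/mu and
beta by default) whose amplitude is suppressed — event-related
desynchronization, ERD — or enhanced (ERS) in chosen channels while chosen
task labels are active. Suppression depth ``d`` scales oscillation amplitude
by ``sqrt(1 - d)`` so band *power* scales by ``1 - d``; negative depths encode
ERS the same way.

Oscillation strength is calibrated against the channel's total background
power (``NoiseModel.osc_power`` is the oscillation-to-background power ratio).
Because the 1/f background spreads its power over 0.5–45 Hz, only a small
fraction of it falls inside any single analysis band, so in-band
oscillation-to-noise is an order of magnitude above the nominal ratio and
injected ERD depths are recoverable from band-power percent changes.

The derived 40-column band-power table (8 electrodes x 5 classical bands)
mirrors the acquisition software's output: band-limited power per channel,
sampled on a sliding window, one task label per row.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bands import BAND_NAMES, DEFAULT_BANDS, BandDefinition, band_by_name, validate_bands
from .errors import ConfigurationError, MibciError
from .labels import CLASS_ORDER, EpochLabel
from .protocol import ProtocolSpec, build_protocol_timeline, timeline_to_label_track

#: default hemisphere assignment of the 8 electrodes
LEFT_HEMISPHERE: tuple[int, ...] = (0, 1, 2, 3)
RIGHT_HEMISPHERE: tuple[int, ...] = (4, 5, 6, 7)
DEFAULT_LATERALITY: dict[int, str] = {
    **{ch: "left" for ch in LEFT_HEMISPHERE},
    **{ch: "right" for ch in RIGHT_HEMISPHERE},
}


@dataclass(frozen=True)
class ERDSpec:
    """One event-related power modulation.

    ``depth`` in (0, 1] suppresses band power by that fraction during the
    given labels on the given channels (ERD); depth in [-1, 0) increases it
    (ERS); 0 is a no-op.
    """

    band: str
    depth: float
    channels: frozenset[int]
    labels: frozenset[EpochLabel]

    def __init__(self, band, depth, channels, labels):
        object.__setattr__(self, "band", band)
        object.__setattr__(self, "depth", float(depth))
        object.__setattr__(self, "channels", frozenset(channels))
        object.__setattr__(self, "labels", frozenset(labels))
        if abs(self.depth) > 1:
            raise ConfigurationError(f"|depth| must be <= 1, got {self.depth}")
        if not self.channels:
            raise ConfigurationError("ERDSpec needs at least one channel")


@dataclass(frozen=True)
class NoiseModel:
    """Background + oscillation calibration.

    rms_uv : RMS amplitude of the 1/f background per channel (microvolts).
    exponent : spectral slope of the background (power ~ 1/f^exponent).
    f_lo, f_hi : support of the background spectrum (Hz).
    osc_power : per-band oscillation power as a multiple of the channel's
        total background power. Bands absent from the map carry no oscillation.
    """

    rms_uv: float = 10.0
    exponent: float = 1.0
    f_lo: float = 0.5
    f_hi: float = 45.0
    osc_power: dict[str, float] = field(
        default_factory=lambda: {"alpha": 2.0, "beta": 2.0}
    )


@dataclass
class Recording:
    """Multichannel time series with a per-sample label track."""

    samples: np.ndarray  # [n_samples, n_channels], microvolts
    fs: float
    labels: np.ndarray  # object array of EpochLabel, length n_samples
    channel_names: list[str]
    seed: int

    def __post_init__(self) -> None:
        if self.samples.ndim != 2:
            raise ConfigurationError("samples must be 2-D [n_samples, n_channels]")
        if len(self.labels) != self.samples.shape[0]:
            raise ConfigurationError("label track length must match n_samples")
        if len(self.channel_names) != self.samples.shape[1]:
            raise ConfigurationError("channel_names length must match n_channels")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class BandPowerTable:
    """The acquisition interchange table: timestamp, per-(channel, band) power, label.

    ``frame`` columns are ``timestamp``, ``ch{i}_{band}`` (channel-major, the
    five bands innermost) and ``label`` (lower-case strings).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.frame.columns)
        if cols[0] != "timestamp" or cols[-1] != "label":
            raise ConfigurationError(
                "band-power frame must start with 'timestamp' and end with 'label'"
            )
        feats = self.feature_columns
        if not feats:
            raise ConfigurationError("band-power frame has no feature columns")
        ts = self.frame["timestamp"].to_numpy()
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise ConfigurationError("timestamps must be strictly increasing")
        if (self.frame[feats].to_numpy() < 0).any():
            raise ConfigurationError("band powers must be non-negative")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("timestamp", "label")]

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def timestamps(self) -> np.ndarray:
        return self.frame["timestamp"].to_numpy()

    @property
    def features(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return np.array([EpochLabel.from_string(s) for s in self.frame["label"]], dtype=object)

    def concat(self, other: "BandPowerTable") -> "BandPowerTable":
        if self.feature_columns != other.feature_columns:
            raise ConfigurationError("cannot concatenate tables with different schemas")
        off = self.frame["timestamp"].iloc[-1] + 1.0
        shifted = other.frame.copy()
        shifted["timestamp"] = shifted["timestamp"] + off
        return BandPowerTable(pd.concat([self.frame, shifted], ignore_index=True))


def feature_column_names(n_channels: int = 8, band_names: tuple[str, ...] = BAND_NAMES) -> list[str]:
    return [f"ch{i + 1}_{b}" for i in range(n_channels) for b in band_names]


def _pink_background(n: int, fs: float, model: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """One channel of 1/f^exponent noise, normalized to exactly model.rms_uv RMS."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    sel = (freqs >= model.f_lo) & (freqs <= model.f_hi)
    shape[sel] = freqs[sel] ** (-model.exponent / 2.0)
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) * shape
    x = np.fft.irfft(spec, n=n)
    x *= model.rms_uv / np.std(x)
    return x


def _narrowband(n: int, fs: float, band: BandDefinition, power: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise band-limited to ``band``, normalized to the given power."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    sel = (freqs >= band.low_hz) & (freqs < band.high_hz)
    spec = np.zeros(len(freqs), dtype=complex)
    spec[sel] = rng.standard_normal(sel.sum()) + 1j * rng.standard_normal(sel.sum())
    x = np.fft.irfft(spec, n=n)
    x *= np.sqrt(power) / np.std(x)
    return x


def generate_recording(
    timeline: list[tuple[EpochLabel, float]],
    erd_specs: list[ERDSpec],
    fs: float = 250.0,
    n_channels: int = 8,
    noise_model: NoiseModel | None = None,
    seed: int = 0,
) -> Recording:
    """Synthesize a labeled multichannel recording for a protocol timeline.

    Deterministic: identical arguments (including ``seed``) give bit-identical
    sample matrices.
    """
    model = noise_model or NoiseModel()
    for spec in erd_specs:
        band_by_name(spec.band)  # raises on unknown band
        if spec.band not in model.osc_power:
            raise ConfigurationError(
                f"ERDSpec targets band {spec.band!r} which carries no oscillation "
                f"(osc_power bands: {sorted(model.osc_power)})"
            )
        bad = [c for c in spec.channels if not (0 <= c < n_channels)]
        if bad:
            raise ConfigurationError(f"ERDSpec channels {bad} outside 0..{n_channels - 1}")
    highest = max(band_by_name(b).high_hz for b in model.osc_power) if model.osc_power else model.f_hi
    if fs < 2 * highest:
        raise ConfigurationError(f"fs={fs} below 2x highest band edge {highest} Hz")

    track = timeline_to_label_track(timeline, fs)
    n = len(track)
    rng = np.random.default_rng(seed)
    background_power = model.rms_uv**2

    label_masks = {lab: (track == lab) for lab in CLASS_ORDER}
    data = np.empty((n_channels, n))
    for ch in range(n_channels):
        data[ch] = _pink_background(n, fs, model, rng)
    for band_name, ratio in model.osc_power.items():
        band = band_by_name(band_name)
        for ch in range(n_channels):
            osc = _narrowband(n, fs, band, ratio * background_power, rng)
            env = np.ones(n)
            for spec in erd_specs:
                if spec.band == band_name and ch in spec.channels:
                    factor = np.sqrt(1.0 - spec.depth)
                    for lab in spec.labels:
                        env[label_masks[lab]] *= factor
            data[ch] += osc * env

    return Recording(
        samples=data.T.copy(),
        fs=fs,
        labels=track,
        channel_names=[f"ch{i + 1}" for i in range(n_channels)],
        seed=seed,
    )


def compute_band_powers(
    recording: Recording,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    window_s: float = 0.5,
    step_s: float = 0.008,
) -> BandPowerTable:
    """Sliding-window band power per channel and band.

    Each channel is band-limited by zeroing the full-record FFT outside the
    band; a row's power is the mean squared amplitude of that component over a
    window of ``window_s`` seconds centred on the row timestamp, emitted every
    ``step_s`` seconds. The row label is the window's majority label, ties
    resolved toward rest. ``window_s`` must span at least two cycles of the
    lowest band's upper edge so the slowest band retains meaningful power.
    """
    validate_bands(bands, recording.fs)
    lowest = min(bands, key=lambda b: b.low_hz)
    if window_s < 2.0 / lowest.high_hz:
        raise ConfigurationError(
            f"window_s={window_s} too short; need >= {2.0 / lowest.high_hz:.3f} s "
            f"(two cycles of the {lowest.name} band's upper edge)"
        )
    fs = recording.fs
    win = int(round(window_s * fs))
    step = max(1, int(round(step_s * fs)))
    n = recording.n_samples
    if win > n:
        raise MibciError(
            f"window of {win} samples exceeds recording length {n}: output would be empty"
        )
    starts = np.arange(0, n - win + 1, step)
    timestamps = (starts + win / 2.0) / fs

    # majority label per window via cumulative indicator counts
    counts = np.empty((len(starts), len(CLASS_ORDER)))
    for j, lab in enumerate(CLASS_ORDER):
        ind = np.concatenate([[0], np.cumsum(recording.labels == lab)])
        counts[:, j] = ind[starts + win] - ind[starts]
    rest_idx = CLASS_ORDER.index(EpochLabel.REST)
    counts[:, rest_idx] += 0.5  # rest wins ties
    row_labels = [CLASS_ORDER[j].value for j in np.argmax(counts, axis=1)]

    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    cols: dict[str, np.ndarray] = {"timestamp": timestamps}
    for ch in range(recording.n_channels):
        spec = np.fft.rfft(recording.samples[:, ch])
        for band in bands:
            mask = (freqs >= band.low_hz) & (freqs < band.high_hz)
            comp = np.fft.irfft(spec * mask, n=n)
            csum = np.concatenate([[0.0], np.cumsum(comp**2)])
            power = (csum[starts + win] - csum[starts]) / win
            cols[f"ch{ch + 1}_{band.name}"] = np.maximum(power, 0.0)
    cols["label"] = row_labels
    return BandPowerTable(pd.DataFrame(cols))


def default_erd_template(
    depth: float = 0.6,
    left_channels: tuple[int, ...] = LEFT_HEMISPHERE,
    right_channels: tuple[int, ...] = RIGHT_HEMISPHERE,
) -> list[ERDSpec]:
    """Contralateral mu/beta ERD template.

    Flexion suppresses the mu (alpha) rhythm and extension the beta rhythm,
    each over the hemisphere contralateral to the moving arm — the classical
    organization of sensorimotor rhythms, with the flexion/extension contrast
    expressed through the band so all four active classes are separable.
    """
    return [
        ERDSpec("alpha", depth, left_channels, {EpochLabel.RIGHT_FLEX}),
        ERDSpec("beta", depth, left_channels, {EpochLabel.RIGHT_EXT}),
        ERDSpec("alpha", depth, right_channels, {EpochLabel.LEFT_FLEX}),
        ERDSpec("beta", depth, right_channels, {EpochLabel.LEFT_EXT}),
    ]


def make_session_fixture(
    n_subjects: int,
    seed: int,
    protocol: ProtocolSpec | None = None,
    depth: float = 0.6,
    fs: float = 250.0,
    window_s: float = 0.5,
    step_s: float = 0.008,
    noise_model: NoiseModel | None = None,
) -> list[BandPowerTable]:
    """Band-power tables for ``n_subjects`` virtual subjects.

    All subjects share the contralateral ERD template at the given depth;
    subject individuality is emulated by log-normal amplitude jitter (sd 0.1
    in log space) of the background RMS and of each band's oscillation power.
    """
    if n_subjects < 1:
        raise ConfigurationError(f"n_subjects must be >= 1, got {n_subjects}")
    protocol = protocol or ProtocolSpec()
    base = noise_model or NoiseModel()
    timeline = build_protocol_timeline(protocol)
    rng = np.random.default_rng(seed)
    tables = []
    for _ in range(n_subjects):
        sub_seed = int(rng.integers(2**31))
        jit = rng.lognormal(0.0, 0.1)
        osc = {b: p * rng.lognormal(0.0, 0.1) for b, p in base.osc_power.items()}
        model = replace(base, rms_uv=base.rms_uv * jit, osc_power=osc)
        rec = generate_recording(
            timeline, default_erd_template(depth), fs=fs, noise_model=model, seed=sub_seed
        )
        tables.append(compute_band_powers(rec, window_s=window_s, step_s=step_s))
    return tables
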