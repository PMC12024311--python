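"""Canonical EEG frequency bands.

The five classical bands cover 0.5–45 Hz; gamma is capped at 45 Hz so that
every band fits under the Nyquist frequency of a 100 Hz acquisition stream.
The mu rhythm (8–12 Hz over sensorimotor cortex) is represented by the alpha
band, and beta spans 13–30 Hz.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low_hz, high_hz)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ConfigurationError(
                f"band {self.name!r}: need 0 < low_hz < high_hz, "
                f"got [{self.low_hz}, {self.high_hz}]"
            )


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def band_by_name(name: str, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> BandDefinition:
    for b in bands:
        if b.name == name:
            return b
    raise ConfigurationError(f"unknown band {name!r}; known: {[b.name for b in bands]}")


def validate_bands(bands: tuple[BandDefinition, ...], fs: float) -> None:
    """Check ordering, non-overlap and the Nyquist bound for a sampling rate."""
    nyq = fs / 2.0
    prev_high = 0.0
    for b in bands:
        if b.low_hz < prev_high:
            raise ConfigurationError(f"bands overlap or are unordered at {b.name!r}")
        if b.high_hz > nyq:
            raise ConfigurationError(
                f"band {b.name!r} upper edge {b.high_hz} Hz exceeds Nyquist {nyq} Hz"
            )
        prev_high = b.high_hz
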