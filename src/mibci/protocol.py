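"""Acquisition-protocol timeline.

One session module (real movement or motor imagery) consists of ``repetitions``
cycles; each cycle performs left-arm flexion, left-arm extension, right-arm
flexion and right-arm extension for ``segment_s`` seconds each, followed by a
rest block of ``rest_s`` seconds. With the defaults (10 repetitions, 5 s
segments, 10 s rests) a module carries 10 x 4 x 5 = 200 s of active task time.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .labels import EpochLabel

#: order of the four active segments within one repetition cycle
CYCLE_ORDER: tuple[EpochLabel, ...] = (
    EpochLabel.LEFT_FLEX,
    EpochLabel.LEFT_EXT,
    EpochLabel.RIGHT_FLEX,
    EpochLabel.RIGHT_EXT,
)


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing of one session module.

    Parameters
    ----------
    repetitions : number of task cycles (default 10).
    segment_s : duration of each flex/extend segment in seconds (default 5).
    rest_s : duration of the rest block closing each cycle (default 10).
    module : "MI" (motor imagery) or "RM" (real movement); metadata only —
        both modules share the same timeline structure.
    """

    repetitions: int = 10
    segment_s: float = 5.0
    rest_s: float = 10.0
    module: str = "MI"

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ConfigurationError(f"repetitions must be >= 1, got {self.repetitions}")
        if self.segment_s <= 0:
            raise ConfigurationError(f"segment_s must be > 0, got {self.segment_s}")
        if self.rest_s < 0:
            raise ConfigurationError(f"rest_s must be >= 0, got {self.rest_s}")
        if self.module not in ("MI", "RM"):
            raise ConfigurationError(f"module must be 'MI' or 'RM', got {self.module!r}")

    @property
    def active_seconds(self) -> float:
        return self.repetitions * len(CYCLE_ORDER) * self.segment_s

    @property
    def total_seconds(self) -> float:
        return self.active_seconds + self.repetitions * self.rest_s


def build_protocol_timeline(spec: ProtocolSpec) -> list[tuple[EpochLabel, float]]:
    """Expand a :class:`ProtocolSpec` into an ordered (label, duration) schedule.

    Each repetition contributes the four active segments in :data:`CYCLE_ORDER`
    followed by one rest block (omitted when ``rest_s == 0``).
    """
    timeline: list[tuple[EpochLabel, float]] = []
    for _ in range(spec.repetitions):
        for label in CYCLE_ORDER:
            timeline.append((label, spec.segment_s))
        if spec.rest_s > 0:
            timeline.append((EpochLabel.REST, spec.rest_s))
    return timeline


def timeline_to_label_track(
    timeline: list[tuple[EpochLabel, float]], fs: float
) -> np.ndarray:
    """Per-sample label array for a timeline sampled at ``fs`` Hz.

    Segment boundaries are placed on the sample grid by rounding cumulative
    times, so the track length never drifts from ``round(total * fs)``.
    """
    if fs <= 0:
        raise ConfigurationError(f"fs must be > 0, got {fs}")
    edges = np.cumsum([0.0] + [d for _, d in timeline])
    idx = np.round(edges * fs).astype(int)
    n = idx[-1]
    track = np.empty(n, dtype=object)
    for (label, _), a, b in zip(timeline, idx[:-1], idx[1:]):
        track[a:b] = label
    return track
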