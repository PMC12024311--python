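"""Real-time classification over a row stream.

Packets (one band-power row each) are buffered into the bundle's window
geometry; every completed hop, the engine extracts features exactly as at
training time, classifies, maps the label to an actuator command and
dispatches it to every registered sink in order. Transports are abstract —
the reference implementations are an in-process queue, a CSV replay source
and a CSV command log — so the loop runs headlessly and deterministically:
the command for a window depends only on rows up to that window's end, and a
replay of the same CSV through the same bundle reproduces the batch
evaluator's labels exactly.
"""
from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator

import numpy as np

from .bundle import ModelBundle
from .errors import ConfigurationError, StreamError
from .labels import EpochLabel


@dataclass(frozen=True)
class StreamPacket:
    timestamp: float
    values: np.ndarray  # one row of band-power values (or raw amplitudes)


class ActuatorCommand(enum.Enum):
    LEFT_FLEX_CMD = "left_flex_cmd"
    LEFT_EXT_CMD = "left_ext_cmd"
    RIGHT_FLEX_CMD = "right_flex_cmd"
    RIGHT_EXT_CMD = "right_ext_cmd"
    NOOP = "noop"


_LABEL_TO_COMMAND: dict[EpochLabel, ActuatorCommand] = {
    EpochLabel.LEFT_FLEX: ActuatorCommand.LEFT_FLEX_CMD,
    EpochLabel.LEFT_EXT: ActuatorCommand.LEFT_EXT_CMD,
    EpochLabel.RIGHT_FLEX: ActuatorCommand.RIGHT_FLEX_CMD,
    EpochLabel.RIGHT_EXT: ActuatorCommand.RIGHT_EXT_CMD,
    EpochLabel.REST: ActuatorCommand.NOOP,
}


def map_label_to_command(label: EpochLabel) -> ActuatorCommand:
    """Fixed bijective label-to-command table; rest maps to no-op."""
    try:
        return _LABEL_TO_COMMAND[label]
    except KeyError:
        raise ConfigurationError(f"not an EpochLabel: {label!r}") from None


# -------------------------------------------------------------- transports
class InProcessTransport:
    """Reference transport: ordered, at-most-once delivery to subscribers."""

    def __init__(self) -> None:
        self._handlers: list[Callable] = []
        self.messages: list = []

    def subscribe(self, handler: Callable) -> None:
        self._handlers.append(handler)

    def push(self, message) -> None:
        self.messages.append(message)
        for h in self._handlers:
            h(message)


class CommandLogSink:
    """Collects (timestamp, command) pairs; optionally persists them as CSV."""

    def __init__(self) -> None:
        self.records: list[tuple[float, ActuatorCommand]] = []

    def __call__(self, message: tuple[float, ActuatorCommand]) -> None:
        self.records.append(message)

    def write_csv(self, path: str | Path) -> Path:
        p = Path(path)
        with open(p, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("timestamp,command\n")
            for ts, cmd in self.records:
                fh.write(f"{ts:.6f},{cmd.value}\n")
        return p


def replay_csv(path: str | Path) -> Iterator[StreamPacket]:
    """Packet iterator over an acquisition CSV (the file-replay transport)."""
    from .io import read_acquisition_csv

    table = read_acquisition_csv(path)
    feats = table.features
    for ts, row in zip(table.timestamps, feats):
        yield StreamPacket(timestamp=float(ts), values=row)


# -------------------------------------------------------------- debounce
def debounce(
    commands: Iterable[ActuatorCommand], min_dwell_windows: int = 1
) -> list[ActuatorCommand]:
    """Suppress actuator chatter: a new command takes effect only after
    appearing in ``min_dwell_windows`` consecutive windows; until then the
    previously emitted state persists (initially no-op)."""
    if min_dwell_windows < 1:
        raise ConfigurationError("min_dwell_windows must be >= 1")
    out: list[ActuatorCommand] = []
    current = ActuatorCommand.NOOP
    candidate: ActuatorCommand | None = None
    streak = 0
    for cmd in commands:
        if cmd == current:
            candidate, streak = None, 0
        elif cmd == candidate:
            streak += 1
            if streak >= min_dwell_windows:
                current = cmd
                candidate, streak = None, 0
        else:
            candidate, streak = cmd, 1
            if streak >= min_dwell_windows:
                current = cmd
                candidate, streak = None, 0
        out.append(current)
    return out


# -------------------------------------------------------------- engine
class StreamEngine:
    """Sliding-window classifier over a packet source."""

    def __init__(
        self,
        bundle: ModelBundle,
        sinks: list[Callable] | None = None,
        min_dwell_windows: int = 1,
    ) -> None:
        self.bundle = bundle
        self.sinks = list(sinks or [])
        if min_dwell_windows < 1:
            raise ConfigurationError("min_dwell_windows must be >= 1")
        self.min_dwell = min_dwell_windows

    def add_sink(self, sink: Callable) -> None:
        self.sinks.append(sink)

    def run(self, source: Iterable[StreamPacket]) -> list[tuple[float, ActuatorCommand]]:
        """Consume the source to exhaustion; one command per completed hop."""
        b = self.bundle
        n_cols = len(b.column_names)
        buf: deque[np.ndarray] = deque(maxlen=b.window_rows)
        times: deque[float] = deque(maxlen=b.window_rows)
        raw_cmds: list[ActuatorCommand] = []
        ends: list[float] = []
        n_seen = 0
        last_ts = -np.inf
        for pkt in source:
            row = np.asarray(pkt.values, dtype=float)
            if row.shape != (n_cols,):
                raise StreamError(
                    f"packet at t={pkt.timestamp} has {row.shape[0] if row.ndim == 1 else row.shape} "
                    f"values; the model bundle expects {n_cols} columns "
                    f"({b.column_names[:3]}...)"
                )
            if pkt.timestamp <= last_ts:
                raise StreamError(
                    f"non-monotone timestamp {pkt.timestamp} after {last_ts}"
                )
            last_ts = pkt.timestamp
            buf.append(row)
            times.append(pkt.timestamp)
            n_seen += 1
            # window starts fall on multiples of hop_rows, as in batch windowing
            if n_seen >= b.window_rows and (n_seen - b.window_rows) % b.hop_rows == 0:
                window = np.stack(buf)
                label = self.classify_window(window)
                raw_cmds.append(map_label_to_command(label))
                ends.append(times[-1])
        emitted = debounce(raw_cmds, self.min_dwell)
        out = list(zip(ends, emitted))
        for msg in out:
            for sink in self.sinks:
                sink(msg)
        return out

    def classify_window(self, window: np.ndarray) -> EpochLabel:
        vec = self.bundle.featurize_window(window)
        return self.bundle.model.predict(vec[None, :])[0]


def run_stream(
    source: Iterable[StreamPacket],
    bundle: ModelBundle,
    sinks: list[Callable] | None = None,
    min_dwell_windows: int = 1,
) -> list[tuple[float, ActuatorCommand]]:
    """Convenience wrapper around :class:`StreamEngine`."""
    return StreamEngine(bundle, sinks=sinks, min_dwell_windows=min_dwell_windows).run(source)
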