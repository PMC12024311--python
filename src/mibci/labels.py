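"""The five task labels of the acquisition protocol.

Every sample of a recording, every row of a band-power table and every
classifier output is one of exactly five states: flexion/extension of either
arm, or rest.
"""
from __future__ import annotations

import enum


class EpochLabel(enum.Enum):
    """Task state attached to each sample/row. Serialized as lower-case strings."""

    RIGHT_EXT = "right_ext"
    RIGHT_FLEX = "right_flex"
    LEFT_EXT = "left_ext"
    LEFT_FLEX = "left_flex"
    REST = "rest"

    def __str__(self) -> str:  # CSV label column
        return self.value

    @classmethod
    def from_string(cls, s: str) -> "EpochLabel":
        try:
            return cls(s.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown label {s!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None

    @property
    def arm(self) -> str | None:
        """'left' / 'right' for active labels, None for rest."""
        if self is EpochLabel.REST:
            return None
        return "left" if self.name.startswith("LEFT") else "right"

    @property
    def movement(self) -> str | None:
        """'flexion' / 'extension' for active labels, None for rest."""
        if self is EpochLabel.REST:
            return None
        return "flexion" if self.name.endswith("FLEX") else "extension"


#: canonical class order used for confusion matrices and one-hot encodings
CLASS_ORDER: tuple[EpochLabel, ...] = (
    EpochLabel.RIGHT_EXT,
    EpochLabel.RIGHT_FLEX,
    EpochLabel.LEFT_EXT,
    EpochLabel.LEFT_FLEX,
    EpochLabel.REST,
)

ACTIVE_LABELS: tuple[EpochLabel, ...] = tuple(
    l for l in CLASS_ORDER if l is not EpochLabel.REST
)
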