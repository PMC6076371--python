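"""Domain types for keystroke metadata streams and clinical mood ratings.

The on-disk and in-memory representations are column-oriented (pandas
DataFrames, see :mod:`keymood.io`); the dataclasses here define the record
schema and carry per-record validation for code that works row-wise.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from datetime import datetime

from .errors import ValidationError


class EventClass(str, enum.Enum):
    """Class of a keyboard event.

    REGULAR, SPACE and BACKSPACE are physical keypresses; AUTOCORRECT is a
    software-initiated correction logged alongside the stream and is *not*
    counted as a keypress. Character content is never recorded: outside the
    backspace key and space bar the entry is anonymized to REGULAR.
    """

    REGULAR = "REGULAR"
    SPACE = "SPACE"
    BACKSPACE = "BACKSPACE"
    AUTOCORRECT = "AUTOCORRECT"


#: Event classes that count as keypresses (feature denominators).
KEYPRESS_CLASSES = frozenset(
    {EventClass.REGULAR, EventClass.SPACE, EventClass.BACKSPACE}
)


class Scale(str, enum.Enum):
    """Clinician-administered mood rating scale."""

    HDRS17 = "HDRS17"
    YMRS = "YMRS"


#: Inclusive valid score range per scale.
SCALE_RANGES: dict[Scale, tuple[int, int]] = {
    Scale.HDRS17: (0, 52),
    Scale.YMRS: (0, 60),
}


def validate_score(scale: Scale, score: int) -> int:
    lo, hi = SCALE_RANGES[Scale(scale)]
    if not (isinstance(score, (int,)) or float(score).is_integer()):
        raise ValidationError(f"{scale} score must be an integer, got {score!r}")
    score = int(score)
    if not lo <= score <= hi:
        raise ValidationError(
            f"{Scale(scale).value} score {score} outside valid range [{lo}, {hi}]"
        )
    return score


@dataclass(frozen=True)
class KeystrokeEvent:
    """One timestamped anonymized keyboard event."""

    subject_id: str
    timestamp: datetime
    event_class: EventClass

    def __post_init__(self):
        if self.timestamp.tzinfo is None:
            raise ValidationError("KeystrokeEvent timestamp must carry a UTC offset")
        object.__setattr__(self, "event_class", EventClass(self.event_class))

    @property
    def is_keypress(self) -> bool:
        return self.event_class in KEYPRESS_CLASSES


@dataclass(frozen=True)
class AccelSample:
    """One timestamped accelerometer displacement triple (m/s^2)."""

    subject_id: str
    timestamp: datetime
    x: float
    y: float
    z: float

    def __post_init__(self):
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"AccelSample.{name} must be finite, got {v!r}")

    @property
    def magnitude(self) -> float:
        """Euclidean magnitude sqrt(x^2 + y^2 + z^2)."""
        return math.sqrt(self.x * self.x + self.y * self.y + self.z * self.z)


@dataclass(frozen=True)
class MoodAssessment:
    """One weekly clinician rating (HDRS-17 or YMRS)."""

    subject_id: str
    assessed_at: datetime
    scale: Scale
    score: int

    def __post_init__(self):
        object.__setattr__(self, "scale", Scale(self.scale))
        object.__setattr__(self, "score", validate_score(self.scale, self.score))
        if self.assessed_at.tzinfo is None:
            raise ValidationError("MoodAssessment.assessed_at must carry a UTC offset")
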