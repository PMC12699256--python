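"""Domain types for dyadic momentary-assessment data.

The study design pairs a patient, who self-reports momentary states (EMA:
ecological momentary assessment), with one support person who reports their
perception of the same states (PeerMA: peer-ceived momentary assessment).
Five constructs are assessed on a visual-analog scale: hope, sleep quality,
fatigue, depression, and pain. Patients additionally wear an activity
monitor producing daily step counts, active minutes by intensity, and sleep
duration.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional


class Polarity(enum.Enum):
    HIGHER_IS_BETTER = "higher_is_better"
    LOWER_IS_BETTER = "lower_is_better"


class Construct(enum.Enum):
    """The five momentary states assessed in each dyad.

    Hope and sleep quality are desirable (higher is better); fatigue,
    depression, and pain are symptoms (lower is better).
    """

    HOPE = "hope"
    SLEEP = "sleep"
    FATIGUE = "fatigue"
    DEPRESSION = "depression"
    PAIN = "pain"

    @property
    def polarity(self) -> Polarity:
        if self in (Construct.HOPE, Construct.SLEEP):
            return Polarity.HIGHER_IS_BETTER
        return Polarity.LOWER_IS_BETTER


class Role(enum.Enum):
    PATIENT = "patient"
    SUPPORT_PERSON = "support_person"


class Trigger(enum.Enum):
    """How an assessment came to exist: a scheduled app prompt, or a
    voluntary self-initiated report."""

    APPLICATION = "application"
    SELF = "self"


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class AssessmentRecord:
    """One momentary self- or peer-report event.

    ``complete`` is False for prompts that expired unanswered; such records
    carry no value. ``confidence`` is the support person's 0-1 slider rating
    of how sure they were of the assessment and is only valid on
    support-person records.
    """

    dyad_id: str
    role: Role
    construct: Construct
    timestamp: dt.datetime
    value_raw: Optional[float] = None
    value_norm: Optional[float] = None
    trigger: Trigger = Trigger.APPLICATION
    complete: bool = True
    confidence: Optional[float] = None
    comment: Optional[str] = None

    def __post_init__(self) -> None:
        if self.confidence is not None:
            if self.role is not Role.SUPPORT_PERSON:
                raise ValidationError(
                    f"confidence set on a {self.role.value} record; only "
                    "support-person records carry confidence"
                )
            if not 0.0 <= self.confidence <= 1.0:
                raise ValidationError(
                    f"confidence {self.confidence} outside [0, 1]"
                )
        if self.value_norm is not None and not 0.0 <= self.value_norm <= 1.0:
            raise ValidationError(f"value_norm {self.value_norm} outside [0, 1]")
        if self.complete and self.value_raw is None:
            raise ValidationError("complete record without a raw value")

    @property
    def date(self) -> dt.date:
        """The local calendar date of the event; all analysis is daily."""
        return self.timestamp.date()

    @property
    def value(self) -> Optional[float]:
        """Normalized value when available, raw otherwise."""
        return self.value_norm if self.value_norm is not None else self.value_raw


_INTENSITIES = ("sedentary", "light", "moderate", "vigorous")


@dataclass(frozen=True)
class WearableDay:
    """One day of activity-monitor output for a patient."""

    dyad_id: str
    date: dt.date
    steps: int
    minutes_by_intensity: Mapping[str, float] = field(default_factory=dict)
    sleep_hours: float = 0.0

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValidationError(f"negative step count {self.steps}")
        unknown = set(self.minutes_by_intensity) - set(_INTENSITIES)
        if unknown:
            raise ValidationError(f"unknown activity intensities {sorted(unknown)}")
        total = sum(self.minutes_by_intensity.values())
        if total > 1440.0 + 1e-9:
            raise ValidationError(f"activity minutes sum to {total} > 1440")
        if any(v < 0 for v in self.minutes_by_intensity.values()):
            raise ValidationError("negative activity minutes")
        if self.sleep_hours < 0:
            raise ValidationError(f"negative sleep duration {self.sleep_hours}")


CONSTRUCTS = tuple(Construct)
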