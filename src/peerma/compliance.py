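"""Compliance accounting: expected prompt counts, answered counts by
trigger type, and response rates.

Response rate = answered (application- plus self-triggered) over expected
scheduled prompts, as an integer percent rounded half-up. Because voluntary
self-triggered reports count toward the numerator, rates above 100% are
legitimate and occur in practice.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .schedule import PromptSchedule, schedule_prompts
from .types import AssessmentRecord, Role, Trigger


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ParticipantSummary:
    dyad_id: str
    role: Role
    days_in_study: int
    weeks: float  # days / 7, one decimal
    expected: int
    answered_application: int
    answered_self: int
    response_rate: int  # integer percent

    @property
    def answered(self) -> int:
        return self.answered_application + self.answered_self


def expected_prompt_count(
    schedule: PromptSchedule,
    enrollment_date: dt.date,
    days_in_study: int,
) -> int:
    """Number of scheduled prompts over the participant's study window."""
    if days_in_study < 0:
        raise ValueError("days_in_study must be >= 0")
    return len(schedule_prompts(schedule, enrollment_date, days_in_study, seed=0))


def response_rate(
    answered_application: int, answered_self: int, expected: int
) -> int:
    """Integer-percent response rate, half-up; may exceed 100."""
    if expected <= 0:
        raise ValueError("response rate undefined for expected <= 0")
    return _round_half_up(
        100.0 * (answered_application + answered_self) / expected
    )


def summarize_participant(
    records: Sequence[AssessmentRecord],
    schedule: PromptSchedule,
    enrollment_date: dt.date,
    days_in_study: int,
) -> ParticipantSummary:
    """Accounting row for one participant from their (deduplicated) log."""
    if not records:
        raise ValueError("no records for participant")
    dyad_id, role = records[0].dyad_id, records[0].role
    answered = [r for r in records if r.complete]
    app = sum(1 for r in answered if r.trigger is Trigger.APPLICATION)
    self_n = sum(1 for r in answered if r.trigger is Trigger.SELF)
    expected = expected_prompt_count(schedule, enrollment_date, days_in_study)
    return ParticipantSummary(
        dyad_id=dyad_id,
        role=role,
        days_in_study=days_in_study,
        weeks=round(days_in_study / 7.0, 1),
        expected=expected,
        answered_application=app,
        answered_self=self_n,
        response_rate=response_rate(app, self_n, expected),
    )


@dataclass(frozen=True)
class StudyTotals:
    """Per-role totals and dispersion over participants (sample SD)."""

    total_answered: Dict[Role, int]
    total_expected: Dict[Role, int]
    total_days: Dict[Role, int]
    mean_answered: Dict[Role, float]
    sd_answered: Dict[Role, float]
    mean_rate: Dict[Role, int]  # integer percent, half-up
    sd_rate: Dict[Role, float]


def study_summary(
    summaries: Sequence[ParticipantSummary],
) -> Tuple[List[ParticipantSummary], StudyTotals]:
    """Study-level accounting over participant rows.

    Totals are plain sums; means/SDs are over participants, with sample
    (n-1) SD. The per-role mean response rate is the mean of the
    per-participant integer rates, rounded half-up.
    """
    rows = list(summaries)
    total_answered, total_expected, total_days = {}, {}, {}
    mean_answered, sd_answered, mean_rate, sd_rate = {}, {}, {}, {}
    for role in Role:
        group = [s for s in rows if s.role is role]
        if not group:
            continue
        answered = np.array([s.answered for s in group], dtype=float)
        rates = np.array([s.response_rate for s in group], dtype=float)
        total_answered[role] = int(answered.sum())
        total_expected[role] = sum(s.expected for s in group)
        total_days[role] = sum(s.days_in_study for s in group)
        mean_answered[role] = float(answered.mean())
        sd_answered[role] = (
            float(answered.std(ddof=1)) if len(group) > 1 else 0.0
        )
        mean_rate[role] = _round_half_up(float(rates.mean()))
        sd_rate[role] = float(rates.std(ddof=1)) if len(group) > 1 else 0.0
    totals = StudyTotals(
        total_answered=total_answered,
        total_expected=total_expected,
        total_days=total_days,
        mean_answered=mean_answered,
        sd_answered=sd_answered,
        mean_rate=mean_rate,
        sd_rate=sd_rate,
    )
    return rows, totals


def summaries_from_accounting_table(table: pd.DataFrame) -> List[ParticipantSummary]:
    """Build participant rows from an accounting table with columns
    dyad_id/participant_id, role, days, expected, answered_application,
    answered_self — recomputing the rate rather than trusting a printed one."""
    id_col = "participant_id" if "participant_id" in table.columns else "dyad_id"
    rows = []
    for _, row in table.iterrows():
        app = int(row["answered_application"])
        self_n = int(row["answered_self"])
        expected = int(row["expected"])
        days = int(row["days"])
        rows.append(
            ParticipantSummary(
                dyad_id=str(row[id_col]),
                role=Role(row["role"]),
                days_in_study=days,
                weeks=round(days / 7.0, 1),
                expected=expected,
                answered_application=app,
                answered_self=self_n,
                response_rate=response_rate(app, self_n, expected),
            )
        )
    return rows


def compliance_table(summaries: Sequence[ParticipantSummary]) -> pd.DataFrame:
    """Tidy accounting table, one row per participant."""
    return pd.DataFrame(
        [
            {
                "participant_id": s.dyad_id,
                "role": s.role.value,
                "days": s.days_in_study,
                "weeks": s.weeks,
                "expected": s.expected,
                "answered_application": s.answered_application,
                "answered_self": s.answered_self,
                "response_rate": s.response_rate,
            }
            for s in summaries
        ]
    )
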