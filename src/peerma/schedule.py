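"""Prompt schedules for time-contingent assessment triggers.

Each construct has its own weekday pattern, weekly period, and delivery
window. The study schedule mixes fixed-clock prompts ("around 10 AM") with
uniformly random windows ("random between 2 PM and 6 PM"), weekly,
bi-weekly, and every-3-weeks periods. Prompts left unattended expire after
one hour.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

from .types import Construct

WEEKDAYS = (
    "monday",
    "tuesday",
    "wednesday",
    "thursday",
    "friday",
    "saturday",
    "sunday",
)


@dataclass(frozen=True)
class ConstructRule:
    """Trigger rule for a single construct.

    ``window_end`` None means a fixed clock time at ``window_start``;
    otherwise the prompt time is uniform in [window_start, window_end).
    ``period_weeks`` of 1/2/3 gives weekly/bi-weekly/every-3-weeks firing,
    counted from the enrollment week.
    """

    weekdays: FrozenSet[str]
    period_weeks: int = 1
    window_start: dt.time = dt.time(10, 0)
    window_end: Optional[dt.time] = None

    def __post_init__(self) -> None:
        if self.period_weeks < 1:
            raise ValueError("period_weeks must be >= 1")
        unknown = set(self.weekdays) - set(WEEKDAYS)
        if unknown:
            raise ValueError(f"unknown weekday(s) {sorted(unknown)}")
        if self.window_end is not None and not self.window_start < self.window_end:
            raise ValueError("random window requires start < end")


@dataclass(frozen=True)
class PromptSchedule:
    rules: Dict[Construct, ConstructRule]
    expiry: dt.timedelta = dt.timedelta(hours=1)


def study_schedule() -> PromptSchedule:
    """The deployed study schedule: hope weekly on Fridays (random 2-6 PM),
    sleep weekly on Tue/Thu/Sun around 10 AM, fatigue weekly on Mondays
    (random 2-6 PM), pain bi-weekly on Tuesdays around 2 PM, depression
    every 3 weeks on Wednesdays around 2 PM."""
    return PromptSchedule(
        rules={
            Construct.HOPE: ConstructRule(
                weekdays=frozenset({"friday"}),
                period_weeks=1,
                window_start=dt.time(14, 0),
                window_end=dt.time(18, 0),
            ),
            Construct.SLEEP: ConstructRule(
                weekdays=frozenset({"tuesday", "thursday", "sunday"}),
                period_weeks=1,
                window_start=dt.time(10, 0),
            ),
            Construct.FATIGUE: ConstructRule(
                weekdays=frozenset({"monday"}),
                period_weeks=1,
                window_start=dt.time(14, 0),
                window_end=dt.time(18, 0),
            ),
            Construct.PAIN: ConstructRule(
                weekdays=frozenset({"tuesday"}),
                period_weeks=2,
                window_start=dt.time(14, 0),
            ),
            Construct.DEPRESSION: ConstructRule(
                weekdays=frozenset({"wednesday"}),
                period_weeks=3,
                window_start=dt.time(14, 0),
            ),
        }
    )


def schedule_prompts(
    schedule: PromptSchedule,
    enrollment_date: dt.date,
    n_days: int,
    seed: int,
) -> List[Tuple[Construct, dt.datetime]]:
    """Enumerate every prompt instant over ``n_days`` starting at enrollment.

    Week k = floor(days since enrollment / 7); a rule with period p fires
    only in weeks divisible by p, so enrollment day itself is eligible.
    Random-window times are reproducible from ``seed``.
    """
    if n_days < 0:
        raise ValueError("n_days must be >= 0")
    rng = np.random.default_rng(seed)
    prompts: List[Tuple[Construct, dt.datetime]] = []
    for day in range(n_days):
        date = enrollment_date + dt.timedelta(days=day)
        week = day // 7
        weekday = WEEKDAYS[date.weekday()]
        for construct in Construct:
            rule = schedule.rules.get(construct)
            if rule is None:
                continue
            if weekday not in rule.weekdays or week % rule.period_weeks != 0:
                continue
            if rule.window_end is None:
                instant = dt.datetime.combine(date, rule.window_start)
            else:
                start = dt.datetime.combine(date, rule.window_start)
                end = dt.datetime.combine(date, rule.window_end)
                offset = rng.uniform(0.0, (end - start).total_seconds())
                instant = start + dt.timedelta(seconds=float(offset))
            prompts.append((construct, instant))
    prompts.sort(key=lambda item: (item[1], item[0].value))
    return prompts
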