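"""Readers and writers for assessment-event logs and daily wearable files.

Both formats are long CSV. The assessment log holds one row per prompt
outcome — answered, expired-unanswered, or voluntarily self-triggered — so
response-rate accounting is computable from a single file. The wearable file
holds one row per patient-day.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .types import (
    AssessmentRecord,
    Construct,
    Role,
    Trigger,
    ValidationError,
    WearableDay,
)

ASSESSMENT_COLUMNS = [
    "dyad_id",
    "role",
    "construct",
    "timestamp",
    "value_raw",
    "value_norm",
    "trigger",
    "complete",
    "confidence",
    "comment",
]

WEARABLE_COLUMNS = [
    "dyad_id",
    "date",
    "steps",
    "sedentary_min",
    "light_min",
    "moderate_min",
    "vigorous_min",
    "sleep_hours",
]


@dataclass(frozen=True)
class LogDialect:
    """Column mapping and raw-scale convention for an assessment log.

    ``raw_scale_max`` admits logs whose slider values were exported on a
    0-100 scale; values are divided by it at read time so the in-memory raw
    scale is always [0, 1]-compatible. The default assumes values are stored
    as given.
    """

    columns: Dict[str, str] = field(default_factory=dict)
    raw_scale_max: float = 1.0

    def source_column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


class FormatError(ValueError):
    """The file as a whole cannot be interpreted (e.g. a missing column)."""


class RowError(ValueError):
    """One or more rows failed validation; carries row-indexed diagnostics."""

    def __init__(self, failures: Sequence[tuple]):
        self.failures = list(failures)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.failures)
        super().__init__(f"{len(self.failures)} invalid row(s): {lines}")


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return str(value)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValueError(f"unparsable boolean {value!r}")


def read_assessment_log(
    path: Union[str, Path], dialect: Optional[LogDialect] = None
) -> List[AssessmentRecord]:
    """Read an assessment log, validating every row.

    Raises :class:`FormatError` if a mandatory column is absent and
    :class:`RowError` listing every offending row otherwise.
    """
    dialect = dialect or LogDialect()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)

    mandatory = ["dyad_id", "role", "construct", "timestamp"]
    missing = [
        c for c in mandatory if dialect.source_column(c) not in frame.columns
    ]
    if missing:
        raise FormatError(f"missing mandatory column(s): {missing}")

    def col(name: str, row) -> Optional[str]:
        src = dialect.source_column(name)
        if src not in frame.columns:
            return None
        text = row[src]
        return None if text == "" else text

    records: List[AssessmentRecord] = []
    failures: List[tuple] = []
    for idx, row in frame.iterrows():
        try:
            raw = _opt_float(col("value_raw", row))
            if raw is not None and dialect.raw_scale_max != 1.0:
                raw = raw / dialect.raw_scale_max
            timestamp_text = col("timestamp", row)
            try:
                timestamp = dt.datetime.fromisoformat(timestamp_text)
            except (TypeError, ValueError):
                raise ValueError(f"unparsable timestamp {timestamp_text!r}")
            complete_text = col("complete", row)
            records.append(
                AssessmentRecord(
                    dyad_id=str(col("dyad_id", row)),
                    role=Role(col("role", row)),
                    construct=Construct(col("construct", row)),
                    timestamp=timestamp,
                    value_raw=raw,
                    value_norm=_opt_float(col("value_norm", row)),
                    trigger=Trigger(col("trigger", row) or "application"),
                    complete=(
                        True if complete_text is None else _parse_bool(complete_text)
                    ),
                    confidence=_opt_float(col("confidence", row)),
                    comment=_opt_str(col("comment", row)),
                )
            )
        except (ValueError, ValidationError, KeyError) as exc:
            failures.append((idx, str(exc)))
    if failures:
        raise RowError(failures)
    return records


def write_assessment_log(
    records: Sequence[AssessmentRecord], path: Union[str, Path]
) -> None:
    """Write records as canonical long CSV (lossless round-trip with
    :func:`read_assessment_log`)."""
    rows = []
    for r in records:
        rows.append(
            {
                "dyad_id": r.dyad_id,
                "role": r.role.value,
                "construct": r.construct.value,
                "timestamp": r.timestamp.isoformat(),
                "value_raw": "" if r.value_raw is None else repr(r.value_raw),
                "value_norm": "" if r.value_norm is None else repr(r.value_norm),
                "trigger": r.trigger.value,
                "complete": str(r.complete).lower(),
                "confidence": "" if r.confidence is None else repr(r.confidence),
                "comment": "" if r.comment is None else r.comment,
            }
        )
    frame = pd.DataFrame(rows, columns=ASSESSMENT_COLUMNS)
    frame.to_csv(path, index=False)


def read_wearable_log(path: Union[str, Path]) -> List[WearableDay]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in WEARABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {missing}")
    days: List[WearableDay] = []
    failures: List[tuple] = []
    for idx, row in frame.iterrows():
        try:
            days.append(
                WearableDay(
                    dyad_id=str(row["dyad_id"]),
                    date=dt.date.fromisoformat(row["date"]),
                    steps=int(float(row["steps"])),
                    minutes_by_intensity={
                        "sedentary": float(row["sedentary_min"]),
                        "light": float(row["light_min"]),
                        "moderate": float(row["moderate_min"]),
                        "vigorous": float(row["vigorous_min"]),
                    },
                    sleep_hours=float(row["sleep_hours"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            failures.append((idx, str(exc)))
    if failures:
        raise RowError(failures)
    return days


def write_wearable_log(
    days: Sequence[WearableDay], path: Union[str, Path]
) -> None:
    rows = []
    for d in days:
        m = d.minutes_by_intensity
        rows.append(
            {
                "dyad_id": d.dyad_id,
                "date": d.date.isoformat(),
                "steps": d.steps,
                "sedentary_min": m.get("sedentary", 0.0),
                "light_min": m.get("light", 0.0),
                "moderate_min": m.get("moderate", 0.0),
                "vigorous_min": m.get("vigorous", 0.0),
                "sleep_hours": d.sleep_hours,
            }
        )
    pd.DataFrame(rows, columns=WEARABLE_COLUMNS).to_csv(path, index=False)
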