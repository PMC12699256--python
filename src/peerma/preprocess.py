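"""Data preparation: same-day dedup, stream alignment, per-person
normalization, and ridge-polynomial imputation to a daily grid.

Sparse weekday-scheduled self-reports are turned into aligned daily series
per dyad and construct. Duplicate same-day reports are collapsed (complete
beats incomplete, then newest wins); the dyad's streams are trimmed to a
common date range anchored at the patient's first report; each person's raw
slider values are min-max rescaled to [0, 1]; and days without a report are
filled by a degree-2 polynomial ridge fit over the observed points.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures

from .types import AssessmentRecord, Construct, Role

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """The two streams of a dyad cannot be brought to a common range."""


class ImputationError(ValueError):
    """Too few observed points to determine the daily curve."""


def deduplicate_daily(
    records: Sequence[AssessmentRecord],
) -> List[AssessmentRecord]:
    """Collapse same-day duplicates per construct to a single record.

    Within each (construct, date) group, incomplete records are dropped when
    a complete one exists; among the remainder the oldest are dropped until
    one record is left. Idempotent.
    """
    groups: Dict[Tuple[Construct, dt.date], List[AssessmentRecord]] = {}
    for record in records:
        groups.setdefault((record.construct, record.date), []).append(record)
    kept: List[AssessmentRecord] = []
    for group in groups.values():
        candidates = [r for r in group if r.complete] or group
        kept.append(max(candidates, key=lambda r: r.timestamp))
    kept.sort(key=lambda r: (r.timestamp, r.construct.value))
    return kept


def align_streams(
    patient_records: Sequence[AssessmentRecord],
    peer_records: Sequence[AssessmentRecord],
) -> Tuple[
    Tuple[dt.date, dt.date], List[AssessmentRecord], List[AssessmentRecord]
]:
    """Trim both streams to a common date range.

    The range starts at the patient's first report and ends at the earlier
    of the two last reports, which maximizes the common set of assessments.
    Returns ``((start, end), patient_trimmed, peer_trimmed)``.
    """
    if not patient_records:
        raise AlignmentError("patient stream is empty")
    if not peer_records:
        raise AlignmentError("support-person stream is empty")
    start = min(r.date for r in patient_records)
    end = min(
        max(r.date for r in patient_records),
        max(r.date for r in peer_records),
    )
    if end < start:
        raise AlignmentError(
            f"no overlap: patient starts {start}, range would end {end}"
        )
    trim = lambda rs: [r for r in rs if start <= r.date <= end]
    return (start, end), trim(patient_records), trim(peer_records)


def normalize_per_person(
    records: Sequence[AssessmentRecord],
    scope: str = "per_construct",
) -> List[AssessmentRecord]:
    """Min-max rescale one person's raw values to [0, 1].

    ``scope='per_construct'`` normalizes each construct against that
    person's own min/max for it (so each construct can reach 0 and 1);
    ``scope='all_constructs'`` pools the person's values across constructs.
    A degenerate group (all values equal) maps to 0.5. Incomplete records
    pass through untouched.
    """
    if scope not in ("per_construct", "all_constructs"):
        raise ValueError(f"unknown scope {scope!r}")

    def group_key(record: AssessmentRecord):
        return record.construct if scope == "per_construct" else None

    bounds: Dict[object, Tuple[float, float]] = {}
    for record in records:
        if not record.complete or record.value_raw is None:
            continue
        key = group_key(record)
        lo, hi = bounds.get(key, (record.value_raw, record.value_raw))
        bounds[key] = (min(lo, record.value_raw), max(hi, record.value_raw))

    out: List[AssessmentRecord] = []
    for record in records:
        if not record.complete or record.value_raw is None:
            out.append(record)
            continue
        lo, hi = bounds[group_key(record)]
        if hi > lo:
            norm = (record.value_raw - lo) / (hi - lo)
        else:
            logger.warning(
                "constant raw values for %s %s group %s; mapping to 0.5",
                record.dyad_id,
                record.role.value,
                group_key(record),
            )
            norm = 0.5
        out.append(
            AssessmentRecord(
                dyad_id=record.dyad_id,
                role=record.role,
                construct=record.construct,
                timestamp=record.timestamp,
                value_raw=record.value_raw,
                value_norm=float(min(1.0, max(0.0, norm))),
                trigger=record.trigger,
                complete=record.complete,
                confidence=record.confidence,
                comment=record.comment,
            )
        )
    return out


def impute_daily_curve(
    observed: Dict[dt.date, float],
    date_range: Tuple[dt.date, dt.date],
    penalty: float = 1.0,
) -> List[float]:
    """Fill every day of ``date_range`` using a degree-2 polynomial ridge fit.

    The day index is rescaled to [0, 1] for conditioning before building
    polynomial features; the intercept is unpenalized. Observed days keep
    their observed value verbatim; missing days take the fitted value
    clipped to [0, 1]. Raises :class:`ImputationError` with fewer than 3
    observed points.
    """
    start, end = date_range
    n_days = (end - start).days + 1
    if n_days < 1:
        raise ValueError("empty date range")
    if any(not start <= d <= end for d in observed):
        raise ValueError("observed date outside the date range")
    if len(observed) < 3:
        raise ImputationError(
            f"{len(observed)} observed point(s); need >= 3 for a degree-2 fit"
        )
    fitted = fit_daily_curve(observed, date_range, penalty)
    series = [float(np.clip(v, 0.0, 1.0)) for v in fitted]
    for date, value in observed.items():
        series[(date - start).days] = float(value)
    return series


def fit_daily_curve(
    observed: Dict[dt.date, float],
    date_range: Tuple[dt.date, dt.date],
    penalty: float = 1.0,
) -> np.ndarray:
    """The pure fitted ridge-polynomial curve over the grid (unclipped,
    ignoring observed-day pass-through) — what the figures plot."""
    start, end = date_range
    n_days = (end - start).days + 1
    span = max(n_days - 1, 1)
    t_obs = np.array([(d - start).days / span for d in sorted(observed)])
    y_obs = np.array([observed[d] for d in sorted(observed)])
    model = make_pipeline(
        PolynomialFeatures(degree=2, include_bias=False),
        Ridge(alpha=penalty),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny-n conditioning warnings
        model.fit(t_obs[:, None], y_obs)
    t_grid = np.arange(n_days) / span
    return model.predict(t_grid[:, None])


@dataclass(frozen=True)
class DyadStreams:
    """Aligned per-construct daily series for one dyad."""

    dyad_id: str
    date_range: Tuple[dt.date, dt.date]
    patient_observed: Dict[Construct, Dict[dt.date, float]]
    peer_observed: Dict[Construct, Dict[dt.date, float]]
    patient_daily: Dict[Construct, List[float]]
    peer_daily: Dict[Construct, List[float]]
    peer_confidence: Dict[Construct, Dict[dt.date, float]]

    @property
    def dates(self) -> List[dt.date]:
        start, end = self.date_range
        return [
            start + dt.timedelta(days=i)
            for i in range((end - start).days + 1)
        ]


def build_dyad_streams(
    patient_records: Sequence[AssessmentRecord],
    peer_records: Sequence[AssessmentRecord],
    scope: str = "per_construct",
    penalty: float = 1.0,
) -> DyadStreams:
    """Run the full preparation chain for one dyad.

    Dedup each stream, normalize per person, align to the common range,
    then impute a daily series per construct and role. Constructs with
    fewer than 3 observed points in a stream fall back to a constant
    (observed-mean) series with a logged warning.
    """
    patient = normalize_per_person(deduplicate_daily(patient_records), scope)
    peer = normalize_per_person(deduplicate_daily(peer_records), scope)
    date_range, patient, peer = align_streams(patient, peer)

    def observed_map(
        records: Sequence[AssessmentRecord], construct: Construct
    ) -> Dict[dt.date, float]:
        return {
            r.date: r.value
            for r in records
            if r.construct is construct and r.complete and r.value is not None
        }

    def daily(observed: Dict[dt.date, float], label: str) -> List[float]:
        n_days = (date_range[1] - date_range[0]).days + 1
        if not observed:
            logger.warning("%s: no observations; flat 0.5 fallback", label)
            return [0.5] * n_days
        try:
            return impute_daily_curve(observed, date_range, penalty)
        except ImputationError:
            logger.warning(
                "%s: %d point(s) < 3; constant-mean fallback",
                label,
                len(observed),
            )
            mean = float(np.mean(list(observed.values())))
            series = [mean] * n_days
            start = date_range[0]
            for date, value in observed.items():
                series[(date - start).days] = float(value)
            return series

    dyad_id = patient[0].dyad_id if patient else "?"
    patient_observed, peer_observed = {}, {}
    patient_daily, peer_daily, peer_confidence = {}, {}, {}
    for construct in Construct:
        patient_observed[construct] = observed_map(patient, construct)
        peer_observed[construct] = observed_map(peer, construct)
        patient_daily[construct] = daily(
            patient_observed[construct], f"{dyad_id}/patient/{construct.value}"
        )
        peer_daily[construct] = daily(
            peer_observed[construct], f"{dyad_id}/peer/{construct.value}"
        )
        peer_confidence[construct] = {
            r.date: r.confidence
            for r in peer
            if r.construct is construct and r.confidence is not None
        }
    return DyadStreams(
        dyad_id=dyad_id,
        date_range=date_range,
        patient_observed=patient_observed,
        peer_observed=peer_observed,
        patient_daily=patient_daily,
        peer_daily=peer_daily,
        peer_confidence=peer_confidence,
    )
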