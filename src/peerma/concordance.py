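"""Similarity and correlation layer for dyadic assessment streams.

Four views of patient/support-person concordance:

* regression-style error metrics (MAE, MSE, RMSE, R^2) treating the
  patient's imputed daily curve as ground truth and the support person's
  curve as its model — R^2 can therefore be strongly negative;
* minimal-importance-difference (MID) binning of |mean difference| at the
  5/10/15% thresholds, 15% being the MID convention for patient-reported
  outcomes;
* Spearman rank correlations (patient vs peer, and self-reports vs daily
  steps), two-sided p via the t approximation;
* a six-bin strength classification of each correlation
  (weak/moderate/high x positive/negative) with study-level count/percent
  summaries.
"""

from __future__ import annotations

import datetime as dt
import enum
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import Construct, WearableDay


class ConstantSeriesError(ValueError):
    """A statistic is undefined because an input series is constant."""


class InsufficientDataError(ValueError):
    """Too few paired observations to compute a statistic."""


@dataclass(frozen=True)
class SimilarityScores:
    mae: float
    mse: float
    rmse: float
    r2: Optional[float]


def similarity_scores(
    patient_daily: Sequence[float], peer_daily: Sequence[float]
) -> SimilarityScores:
    """Error metrics with the patient's curve as ground truth.

    r2 = 1 - SS_res/SS_tot with SS_tot about the patient mean; returned as
    None-free only when the patient series is non-constant (a constant
    ground truth makes R^2 undefined; the error metrics are still returned
    via the raised error's ``scores`` attribute-free contract: callers who
    need them on constant input should catch :class:`ConstantSeriesError`
    and use :func:`error_metrics`).
    """
    p = np.asarray(patient_daily, dtype=float)
    s = np.asarray(peer_daily, dtype=float)
    if p.shape != s.shape:
        raise ValueError("series lengths differ")
    if p.size < 2:
        raise InsufficientDataError("need >= 2 points")
    mae, mse, rmse = error_metrics(p, s)
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    if ss_tot == 0.0:
        raise ConstantSeriesError(
            "patient series is constant; R^2 undefined "
            f"(mae={mae:.6g}, mse={mse:.6g}, rmse={rmse:.6g})"
        )
    r2 = 1.0 - float(np.sum((p - s) ** 2)) / ss_tot
    return SimilarityScores(mae=mae, mse=mse, rmse=rmse, r2=r2)


def error_metrics(
    patient: Sequence[float], peer: Sequence[float]
) -> Tuple[float, float, float]:
    """(MAE, MSE, RMSE) of the peer series against the patient series."""
    p = np.asarray(patient, dtype=float)
    s = np.asarray(peer, dtype=float)
    mae = float(np.mean(np.abs(p - s)))
    mse = float(np.mean((p - s) ** 2))
    return mae, mse, math.sqrt(mse)


MID_BINS = ("<=5%", "<=10%", "<=15%", ">15%")


def mean_difference_bin(mean_patient: float, mean_peer: float) -> str:
    """Bin |mean difference| at the 5/10/15% minimal-importance thresholds.

    Bins are mutually exclusive and upper-bound inclusive; the difference is
    rounded to 9 decimals first so binary-float artifacts cannot push an
    exact boundary (e.g. 0.82 - 0.72) across a bin.
    """
    for value in (mean_patient, mean_peer):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"mean {value} outside [0, 1]")
    d = round(abs(mean_patient - mean_peer), 9)
    if d <= 0.05:
        return "<=5%"
    if d <= 0.10:
        return "<=10%"
    if d <= 0.15:
        return "<=15%"
    return ">15%"


_EXACT_PERMUTATION_MAX_N = 7


def spearman_rs(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties are average-ranked. For n <= 7 the p-value is computed by exact
    enumeration of all permutations (the t approximation is unreliable at
    such sizes); for larger n the standard two-sided t-distribution
    approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantSeriesError("correlation undefined for constant input")
    rs = float(stats.spearmanr(x, y).statistic)
    if x.size <= _EXACT_PERMUTATION_MAX_N:
        return rs, _exact_permutation_p(x, y, rs)
    return rs, float(stats.spearmanr(x, y).pvalue)


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, rs_obs: float) -> float:
    """Two-sided exact p: fraction of all n! pairings of the y ranks whose
    |rs| reaches |rs_obs| (to within a float-noise margin)."""
    import itertools

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    denom_x = float(rx_c @ rx_c)
    threshold = abs(rs_obs) - 1e-12
    hits = total = 0
    for perm in itertools.permutations(ry):
        ry_p = np.asarray(perm) - ry.mean()
        denom = math.sqrt(denom_x * float(ry_p @ ry_p))
        rs_p = float(rx_c @ ry_p) / denom
        total += 1
        if abs(rs_p) >= threshold:
            hits += 1
    return hits / total


class StrengthClass(enum.Enum):
    HIGHLY_POSITIVE = "highly_positive"
    MODERATELY_POSITIVE = "moderately_positive"
    WEAKLY_POSITIVE = "weakly_positive"
    WEAKLY_NEGATIVE = "weakly_negative"
    MODERATELY_NEGATIVE = "moderately_negative"
    HIGHLY_NEGATIVE = "highly_negative"


def classify_strength(rs: float) -> StrengthClass:
    """Six-bin strength class of a correlation coefficient.

    The published interval bounds (0.00-0.33 | 0.34-0.66 | 0.67-1.00 and
    mirrored) partition the line only at 2-decimal resolution, so the value
    is rounded half-up to 2 decimals first (0.335 -> 0.34 -> moderate).
    Exactly 0 counts as weakly positive.
    """
    if not -1.0 <= rs <= 1.0:
        raise ValueError(f"correlation {rs} outside [-1, 1]")
    cents = int(
        Decimal(repr(rs)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
        * 100
    )
    if cents >= 67:
        return StrengthClass.HIGHLY_POSITIVE
    if cents >= 34:
        return StrengthClass.MODERATELY_POSITIVE
    if cents >= 0:
        return StrengthClass.WEAKLY_POSITIVE
    if cents >= -33:
        return StrengthClass.WEAKLY_NEGATIVE
    if cents >= -66:
        return StrengthClass.MODERATELY_NEGATIVE
    return StrengthClass.HIGHLY_NEGATIVE


def classification_summary(correlations: pd.DataFrame) -> pd.DataFrame:
    """Count and percentage of each strength class per construct + overall.

    ``correlations`` is long-form with columns ``construct`` and ``rs``.
    Percentages are over the total number of correlations, rounded half-up
    to integers. Returns one row per strength class with per-construct
    ``<construct>_n`` / ``<construct>_pct`` columns and ``total_n`` /
    ``total_pct``.
    """
    total = len(correlations)
    if total == 0:
        raise ValueError("no correlations to summarize")
    classes = [classify_strength(rs) for rs in correlations["rs"]]
    frame = correlations.assign(strength=[c.value for c in classes])
    constructs = [c.value for c in Construct if c.value in set(frame["construct"])]
    rows = []
    for cls in StrengthClass:
        row: Dict[str, object] = {"strength": cls.value}
        for construct in constructs:
            sub = frame[frame["construct"] == construct]
            n = int((sub["strength"] == cls.value).sum())
            row[f"{construct}_n"] = n
            row[f"{construct}_pct"] = _pct(n, len(sub))
        n_total = int((frame["strength"] == cls.value).sum())
        row["total_n"] = n_total
        row["total_pct"] = _pct(n_total, total)
        rows.append(row)
    return pd.DataFrame(rows)


def _pct(n: int, total: int) -> int:
    return int(math.floor(100.0 * n / total + 0.5))


def mid_bin_summary(table6_means: pd.DataFrame) -> pd.DataFrame:
    """MID-bin counts per construct from a per-person means table
    (columns dyad_id, role, construct, mean). One row per bin."""
    wide = table6_means.pivot_table(
        index=["dyad_id", "construct"], columns="role", values="mean"
    ).reset_index()
    bins = [
        mean_difference_bin(row["patient"], row["support_person"])
        for _, row in wide.iterrows()
    ]
    wide = wide.assign(mid_bin=bins)
    constructs = [c.value for c in Construct]
    rows = []
    for bin_label in MID_BINS:
        row: Dict[str, object] = {"mid_bin": bin_label}
        for construct in constructs:
            sub = wide[wide["construct"] == construct]
            n = int((sub["mid_bin"] == bin_label).sum())
            row[f"{construct}_n"] = n
            row[f"{construct}_pct"] = _pct(n, len(sub)) if len(sub) else 0
        rows.append(row)
    return pd.DataFrame(rows)


def ema_wearable_correlation(
    assessments: Mapping[Construct, Mapping[dt.date, float]],
    wearable: Sequence[WearableDay],
    pairing: str = "observed_days",
    daily: Optional[Mapping[Construct, Sequence[float]]] = None,
    date_range: Optional[Tuple[dt.date, dt.date]] = None,
) -> Dict[Construct, Tuple[float, float]]:
    """Spearman correlation of each construct's values with daily steps.

    ``observed_days`` pairs each observed assessment day with that calendar
    day's step count; ``imputed_daily`` pairs every grid day of the imputed
    series (requires ``daily`` and ``date_range``). Constructs with fewer
    than 3 pairable days raise :class:`InsufficientDataError`.
    """
    steps_by_date = {w.date: float(w.steps) for w in wearable}
    out: Dict[Construct, Tuple[float, float]] = {}
    for construct in assessments:
        if pairing == "observed_days":
            pairs = [
                (value, steps_by_date[date])
                for date, value in sorted(assessments[construct].items())
                if date in steps_by_date
            ]
        elif pairing == "imputed_daily":
            if daily is None or date_range is None:
                raise ValueError(
                    "imputed_daily pairing requires daily series and range"
                )
            start = date_range[0]
            series = daily[construct]
            pairs = [
                (series[i], steps_by_date[start + dt.timedelta(days=i)])
                for i in range(len(series))
                if start + dt.timedelta(days=i) in steps_by_date
            ]
        else:
            raise ValueError(f"unknown pairing {pairing!r}")
        if len(pairs) < 3:
            raise InsufficientDataError(
                f"{construct.value}: {len(pairs)} pairable day(s) < 3"
            )
        values, steps = zip(*pairs)
        out[construct] = spearman_rs(values, steps)
    return out


@dataclass(frozen=True)
class DyadConstructReport:
    """Everything the analysis reports for one (dyad, construct) pair."""

    dyad_id: str
    construct: Construct
    similarity: Optional[SimilarityScores]
    mean_patient: float
    mean_peer: float
    mid_bin: str
    rs: Optional[float]
    p: Optional[float]
    strength: Optional[StrengthClass]


def dyad_construct_report(
    dyad_id: str,
    construct: Construct,
    patient_daily: Sequence[float],
    peer_daily: Sequence[float],
    patient_observed: Mapping[dt.date, float],
    peer_observed: Mapping[dt.date, float],
    pairing: str = "observed_days",
) -> DyadConstructReport:
    """Similarity on the imputed curves; correlation on same-day observed
    pairs by default (``pairing='imputed_daily'`` correlates the curves)."""
    try:
        similarity = similarity_scores(patient_daily, peer_daily)
    except (ConstantSeriesError, InsufficientDataError):
        similarity = None
    mean_patient = float(np.mean(patient_daily))
    mean_peer = float(np.mean(peer_daily))
    mid = mean_difference_bin(
        min(1.0, max(0.0, mean_patient)), min(1.0, max(0.0, mean_peer))
    )
    if pairing == "imputed_daily":
        x, y = list(patient_daily), list(peer_daily)
    else:
        common = sorted(set(patient_observed) & set(peer_observed))
        x = [patient_observed[d] for d in common]
        y = [peer_observed[d] for d in common]
    try:
        rs, p = spearman_rs(x, y)
        strength = classify_strength(max(-1.0, min(1.0, rs)))
    except (ConstantSeriesError, InsufficientDataError):
        rs, p, strength = None, None, None
    return DyadConstructReport(
        dyad_id=dyad_id,
        construct=construct,
        similarity=similarity,
        mean_patient=mean_patient,
        mean_peer=mean_peer,
        mid_bin=mid,
        rs=rs,
        p=p,
        strength=strength,
    )
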