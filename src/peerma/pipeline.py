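"""Pipeline orchestration: simulate/ingest -> preprocess -> analyze -> report.

A :class:`PipelineConfig` (loadable from YAML/JSON) drives a deterministic
run that writes tidy CSVs — per-dyad concordance, the MID-bin table, the
correlation-strength summaries for both the dyad and steps analyses, and
per-dyad aligned daily-series exports — plus a JSON manifest recording
parameters, warnings, and a content digest for every output file.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import concordance as cc
from .compliance import compliance_table, summaries_from_accounting_table
from .fixtures import load_fixtures
from .io import read_assessment_log, read_wearable_log
from .preprocess import DyadStreams, build_dyad_streams
from .simulate import SimulationConfig, simulate_study
from .types import AssessmentRecord, Construct, Role, WearableDay

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """The pipeline configuration is incomplete or inconsistent."""


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    assessment_log: Optional[str] = None
    wearable_log: Optional[str] = None
    simulate: bool = False
    seed: int = 0
    n_dyads: int = 7
    n_days: int = 140
    scope: str = "per_construct"
    penalty: float = 1.0
    pairing: str = "observed_days"
    with_wearable: bool = True

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate and self.assessment_log is None:
            raise ConfigurationError(
                "either simulate=true or an assessment_log path is required"
            )
        if self.assessment_log and not Path(self.assessment_log).exists():
            raise ConfigurationError(
                f"assessment log not found: {self.assessment_log}"
            )
        if (
            not self.simulate
            and self.with_wearable
            and self.wearable_log is None
        ):
            raise ConfigurationError(
                "with_wearable=true requires a wearable_log path (or simulate)"
            )
        if self.wearable_log and not Path(self.wearable_log).exists():
            raise ConfigurationError(
                f"wearable log not found: {self.wearable_log}"
            )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _split_by_dyad_role(
    records: Sequence[AssessmentRecord],
) -> Dict[Tuple[str, Role], List[AssessmentRecord]]:
    out: Dict[Tuple[str, Role], List[AssessmentRecord]] = {}
    for r in records:
        out.setdefault((r.dyad_id, r.role), []).append(r)
    return out


def export_dyad_series(
    streams: DyadStreams, wearable: Sequence[WearableDay]
) -> pd.DataFrame:
    """Tidy per-day export behind the study's time-series figures.

    One row per date x construct x role with the observed value (empty on
    non-report days), the imputed daily value, the support person's
    confidence (peer rows only), and the day's steps / sleep hours (empty —
    never zero — on days without wearable data).
    """
    steps = {w.date: w.steps for w in wearable}
    sleep = {w.date: w.sleep_hours for w in wearable}
    rows = []
    for i, date in enumerate(streams.dates):
        for construct in Construct:
            for role, observed, daily in (
                ("patient", streams.patient_observed, streams.patient_daily),
                ("support_person", streams.peer_observed, streams.peer_daily),
            ):
                confidence = (
                    streams.peer_confidence[construct].get(date)
                    if role == "support_person"
                    else None
                )
                rows.append(
                    {
                        "dyad_id": streams.dyad_id,
                        "date": date.isoformat(),
                        "construct": construct.value,
                        "role": role,
                        "observed_value": observed[construct].get(date),
                        "imputed_value": daily[construct][i],
                        "confidence": confidence,
                        "steps": steps.get(date),
                        "sleep_hours": sleep.get(date),
                    }
                )
    return pd.DataFrame(rows)


def analyze_streams(
    all_streams: Sequence[DyadStreams],
    wearable_by_dyad: Dict[str, List[WearableDay]],
    pairing: str = "observed_days",
) -> Dict[str, pd.DataFrame]:
    """Concordance layer over prepared streams.

    Returns the per-(dyad, construct) concordance table, the MID-bin
    summary, the dyad-correlation strength summary, and — when wearable
    data exists — the steps-correlation table and its strength summary.
    """
    rows = []
    for streams in all_streams:
        for construct in Construct:
            report = cc.dyad_construct_report(
                streams.dyad_id,
                construct,
                streams.patient_daily[construct],
                streams.peer_daily[construct],
                streams.patient_observed[construct],
                streams.peer_observed[construct],
                pairing=pairing,
            )
            sim = report.similarity
            rows.append(
                {
                    "dyad_id": report.dyad_id,
                    "construct": construct.value,
                    "mae": sim.mae if sim else None,
                    "mse": sim.mse if sim else None,
                    "rmse": sim.rmse if sim else None,
                    "r2": sim.r2 if sim else None,
                    "mean_patient": report.mean_patient,
                    "mean_peer": report.mean_peer,
                    "mid_bin": report.mid_bin,
                    "rs": report.rs,
                    "p": report.p,
                    "strength": report.strength.value if report.strength else None,
                }
            )
    concordance = pd.DataFrame(rows)

    means = pd.concat(
        [
            concordance[["dyad_id", "construct", "mean_patient"]]
            .rename(columns={"mean_patient": "mean"})
            .assign(role="patient"),
            concordance[["dyad_id", "construct", "mean_peer"]]
            .rename(columns={"mean_peer": "mean"})
            .assign(role="support_person"),
        ]
    )
    mid_summary = cc.mid_bin_summary(means)

    valid = concordance.dropna(subset=["rs"])[["dyad_id", "construct", "rs"]]
    dyad_class = (
        cc.classification_summary(valid) if len(valid) else pd.DataFrame()
    )

    out = {
        "concordance": concordance,
        "mid_summary": mid_summary,
        "dyad_classification": dyad_class,
    }

    steps_rows = []
    for streams in all_streams:
        wearable = wearable_by_dyad.get(streams.dyad_id, [])
        if not wearable:
            continue
        try:
            result = cc.ema_wearable_correlation(
                streams.patient_observed,
                wearable,
                pairing=pairing if pairing == "imputed_daily" else "observed_days",
                daily=streams.patient_daily,
                date_range=streams.date_range,
            )
        except cc.InsufficientDataError as exc:
            logger.warning("steps correlation skipped: %s", exc)
            continue
        for construct, (rs, p) in result.items():
            steps_rows.append(
                {
                    "dyad_id": streams.dyad_id,
                    "construct": construct.value,
                    "rs": rs,
                    "p": p,
                    "strength": cc.classify_strength(
                        max(-1.0, min(1.0, rs))
                    ).value,
                }
            )
    if steps_rows:
        steps_corr = pd.DataFrame(steps_rows)
        out["steps_correlations"] = steps_corr
        out["steps_classification"] = cc.classification_summary(
            steps_corr[["dyad_id", "construct", "rs"]]
        )
    return out


def fixture_tables() -> Dict[str, pd.DataFrame]:
    """Re-derive the study's summary tables from the packaged printed
    tables: MID bins from the per-person means, strength summaries from the
    two correlation matrices, and the accounting table with recomputed
    rates."""
    fixtures = load_fixtures()
    rows = summaries_from_accounting_table(fixtures.table5_accounting)
    return {
        "mid_summary": cc.mid_bin_summary(fixtures.table6_means),
        "dyad_classification": cc.classification_summary(
            fixtures.table10_dyad_correlations
        ),
        "steps_classification": cc.classification_summary(
            fixtures.table8_steps_correlations
        ),
        "compliance": compliance_table(rows),
    }


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute the configured pipeline and write every output CSV.

    Returns the run manifest: parameters, stage timings and record counts,
    warnings, and a SHA-256 digest per output file. Deterministic for a
    fixed (config, seed).
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "parameters": asdict(config),
        "stages": {},
        "warnings": [],
        "outputs": {},
    }

    t0 = time.perf_counter()
    if config.simulate:
        sim_config = SimulationConfig(
            n_dyads=config.n_dyads, n_days=config.n_days, seed=config.seed
        )
        dyads = simulate_study(sim_config)
        records = [
            r
            for d in dyads
            for r in list(d.patient_records) + list(d.peer_records)
        ]
        wearable = [w for d in dyads for w in d.wearable]
    else:
        records = read_assessment_log(config.assessment_log)
        wearable = (
            read_wearable_log(config.wearable_log)
            if config.wearable_log
            else []
        )
    manifest["stages"]["ingest"] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "n_records": len(records),
        "n_wearable_days": len(wearable),
    }

    t0 = time.perf_counter()
    by_participant = _split_by_dyad_role(records)
    dyad_ids = sorted(
        {d for d, _ in by_participant},
        key=lambda s: (len(s), s),
    )
    all_streams: List[DyadStreams] = []
    for dyad_id in dyad_ids:
        patient = by_participant.get((dyad_id, Role.PATIENT), [])
        peer = by_participant.get((dyad_id, Role.SUPPORT_PERSON), [])
        if not patient or not peer:
            manifest["warnings"].append(
                f"dyad {dyad_id}: missing a stream; skipped"
            )
            continue
        try:
            all_streams.append(
                build_dyad_streams(
                    patient, peer, scope=config.scope, penalty=config.penalty
                )
            )
        except ValueError as exc:
            raise RuntimeError(
                f"preprocess failed for dyad {dyad_id}: {exc}"
            ) from exc
    manifest["stages"]["preprocess"] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "n_dyads": len(all_streams),
    }

    t0 = time.perf_counter()
    wearable_by_dyad: Dict[str, List[WearableDay]] = {}
    for w in wearable:
        wearable_by_dyad.setdefault(w.dyad_id, []).append(w)
    tables = analyze_streams(
        all_streams, wearable_by_dyad, pairing=config.pairing
    )
    manifest["stages"]["analyze"] = {
        "seconds": round(time.perf_counter() - t0, 3)
    }

    for name, frame in tables.items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        manifest["outputs"][str(path)] = _digest(path)
    for streams in all_streams:
        frame = export_dyad_series(
            streams, wearable_by_dyad.get(streams.dyad_id, [])
        )
        path = out_dir / f"dyad_{streams.dyad_id}_series.csv"
        frame.to_csv(path, index=False)
        manifest["outputs"][str(path)] = _digest(path)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
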