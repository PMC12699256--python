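"""Synthetic dyad generator with known ground truth.

No raw data accompanies the original study, so every downstream stage is
exercised against simulated dyads: each patient carries a latent daily
trajectory in [0, 1] per construct (a mean-reverting Gaussian walk, clipped,
whose autocorrelation mimics slow-moving clinical states); prompts follow
the deployed weekday schedule; compliance is Bernoulli per prompt with
voluntary self-triggered reports arriving Poisson per day; the support
person observes the patient's latent state through a bias + noise (+
optional whole-day lag) channel and rates their confidence; and the
wearable stream couples daily steps and sleep duration linearly to the
latent states.

Default parameters are chosen to emulate the study population: 7 dyads over
~20 weeks, patient/peer answer probabilities matching the observed mean
response rates, and step couplings whose signs match the reported
steps-vs-symptom correlations.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .schedule import PromptSchedule, schedule_prompts, study_schedule
from .types import AssessmentRecord, Construct, Role, Trigger, WearableDay


@dataclass(frozen=True)
class LatentModel:
    """Mean-reverting bounded walk for one construct.

    x[t+1] = x[t] + reversion * (baseline - x[t]) + N(0, volatility),
    clipped to [0, 1]; x[0] = baseline. The stationary mean is the baseline.
    """

    baseline: float = 0.5
    reversion: float = 0.1
    volatility: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline <= 1.0:
            raise ValueError("baseline must lie in [0, 1]")
        if not 0.0 <= self.reversion <= 1.0:
            raise ValueError("reversion must lie in [0, 1]")
        if self.volatility < 0.0:
            raise ValueError("volatility must be >= 0")


@dataclass(frozen=True)
class PeerModel:
    """How the support person perceives the patient's latent state.

    Perceived value = clip(latent(day - lag_days) + bias + N(0, noise_sd)).
    Confidence is drawn from a clipped normal, independent of the error
    magnitude unless ``confidence_tracks_error`` is set (then larger |error|
    lowers the draw's mean — a sensitivity-study option).
    """

    bias: float = 0.05
    noise_sd: float = 0.15
    lag_days: int = 0
    confidence_mean: float = 0.8
    confidence_sd: float = 0.15
    confidence_tracks_error: bool = False

    def __post_init__(self) -> None:
        if not -1.0 <= self.bias <= 1.0:
            raise ValueError("bias must lie in [-1, 1]")
        if self.noise_sd < 0.0 or self.lag_days < 0:
            raise ValueError("noise_sd and lag_days must be >= 0")


@dataclass(frozen=True)
class ComplianceModel:
    """Answer probabilities per role and the voluntary self-trigger rate
    (reports per day, Poisson)."""

    p_patient: float = 0.63
    p_support: float = 0.74
    self_trigger_rate: float = 0.25

    def __post_init__(self) -> None:
        for p in (self.p_patient, self.p_support):
            if not 0.0 <= p <= 1.0:
                raise ValueError("answer probabilities must lie in [0, 1]")
        if self.self_trigger_rate < 0.0:
            raise ValueError("self_trigger_rate must be >= 0")

    def p_for(self, role: Role) -> float:
        return self.p_patient if role is Role.PATIENT else self.p_support


@dataclass(frozen=True)
class WearableModel:
    """Linear coupling of daily steps and sleep hours to the latent states.

    steps(day) = max(0, baseline_steps + sum_c weight_c * latent_c(day) +
    N(0, step_noise_sd)). Sleep hours couple to the sleep-quality construct.
    Step weights default to negative for the symptom constructs and positive
    for hope, matching the direction of the observed steps correlations.
    """

    baseline_steps: float = 6000.0
    step_weights: Dict[Construct, float] = field(
        default_factory=lambda: {
            Construct.HOPE: 1500.0,
            Construct.SLEEP: 500.0,
            Construct.FATIGUE: -3000.0,
            Construct.DEPRESSION: -1500.0,
            Construct.PAIN: -2000.0,
        }
    )
    step_noise_sd: float = 1000.0
    sleep_base_hours: float = 5.0
    sleep_gain_hours: float = 3.5
    sleep_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.step_noise_sd < 0.0 or self.sleep_noise_sd < 0.0:
            raise ValueError("noise SDs must be >= 0")


_DEFAULT_BASELINES = {
    Construct.HOPE: 0.60,
    Construct.SLEEP: 0.68,
    Construct.FATIGUE: 0.45,
    Construct.DEPRESSION: 0.34,
    Construct.PAIN: 0.37,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full study-generation configuration with study-like defaults."""

    n_dyads: int = 7
    n_days: int = 140
    seed: int = 0
    enrollment_date: dt.date = dt.date(2019, 9, 2)  # a Monday
    latent: Dict[Construct, LatentModel] = field(
        default_factory=lambda: {
            c: LatentModel(baseline=b) for c, b in _DEFAULT_BASELINES.items()
        }
    )
    peer: PeerModel = field(default_factory=PeerModel)
    compliance: ComplianceModel = field(default_factory=ComplianceModel)
    wearable: WearableModel = field(default_factory=WearableModel)
    schedule: PromptSchedule = field(default_factory=study_schedule)

    def __post_init__(self) -> None:
        if self.n_dyads < 1 or self.n_days < 1:
            raise ValueError("n_dyads and n_days must be positive")


@dataclass(frozen=True)
class LatentTrajectory:
    construct: Construct
    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not 0.0 <= v <= 1.0 for v in self.values):
            raise ValueError("latent values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)


def simulate_latent(
    config: SimulationConfig, construct: Construct, seed: int
) -> LatentTrajectory:
    """Draw one clipped mean-reverting daily trajectory of length n_days."""
    model = config.latent[construct]
    rng = np.random.default_rng(seed)
    values = np.empty(config.n_days)
    x = model.baseline
    for t in range(config.n_days):
        values[t] = x
        shock = rng.normal(0.0, model.volatility) if model.volatility > 0 else 0.0
        x = x + model.reversion * (model.baseline - x) + shock
        x = min(1.0, max(0.0, x))
    return LatentTrajectory(construct=construct, values=tuple(values))


def simulate_responses(
    prompts: Sequence[Tuple[Construct, dt.datetime]],
    latent: Dict[Construct, LatentTrajectory],
    config: SimulationConfig,
    role: Role,
    seed: int,
    dyad_id: str = "1",
    enrollment_date: Optional[dt.date] = None,
) -> List[AssessmentRecord]:
    """Turn scheduled prompts into answered / expired assessment records.

    Each prompt is answered with the role's compliance probability;
    unanswered prompts yield ``complete=False`` records with no value.
    Patient answers report the latent value of that day exactly; peer
    answers pass through the peer-perception channel. Self-triggered
    reports (always complete) arrive Poisson per day, cycling through the
    constructs uniformly at random.
    """
    start = enrollment_date or config.enrollment_date
    n_days = config.n_days
    rng = np.random.default_rng(seed)
    p_answer = config.compliance.p_for(role)
    peer = config.peer

    def day_index(instant: dt.datetime) -> int:
        day = (instant.date() - start).days
        if not 0 <= day < n_days:
            raise ValueError(
                f"prompt on {instant.date()} outside the simulated span"
            )
        return day

    def draw_value(construct: Construct, day: int) -> Tuple[float, Optional[float]]:
        series = latent[construct].values
        if role is Role.PATIENT:
            return series[day], None
        src_day = max(0, day - peer.lag_days)
        noise = rng.normal(0.0, peer.noise_sd) if peer.noise_sd > 0 else 0.0
        value = min(1.0, max(0.0, series[src_day] + peer.bias + noise))
        conf_mean = peer.confidence_mean
        if peer.confidence_tracks_error:
            conf_mean = conf_mean - abs(noise)
        confidence = min(
            1.0, max(0.0, rng.normal(conf_mean, peer.confidence_sd))
        )
        return value, float(confidence)

    records: List[AssessmentRecord] = []
    for construct, instant in prompts:
        day = day_index(instant)
        if rng.random() < p_answer:
            value, confidence = draw_value(construct, day)
            records.append(
                AssessmentRecord(
                    dyad_id=dyad_id,
                    role=role,
                    construct=construct,
                    timestamp=instant,
                    value_raw=float(value),
                    trigger=Trigger.APPLICATION,
                    complete=True,
                    confidence=confidence,
                )
            )
        else:
            records.append(
                AssessmentRecord(
                    dyad_id=dyad_id,
                    role=role,
                    construct=construct,
                    timestamp=instant,
                    value_raw=None,
                    trigger=Trigger.APPLICATION,
                    complete=False,
                )
            )

    rate = config.compliance.self_trigger_rate
    if rate > 0:
        constructs = list(Construct)
        for day in range(n_days):
            for _ in range(int(rng.poisson(rate))):
                construct = constructs[int(rng.integers(len(constructs)))]
                seconds = int(rng.integers(8 * 3600, 22 * 3600))
                instant = dt.datetime.combine(
                    start + dt.timedelta(days=day), dt.time(0, 0)
                ) + dt.timedelta(seconds=seconds)
                value, confidence = draw_value(construct, day)
                records.append(
                    AssessmentRecord(
                        dyad_id=dyad_id,
                        role=role,
                        construct=construct,
                        timestamp=instant,
                        value_raw=float(value),
                        trigger=Trigger.SELF,
                        complete=True,
                        confidence=confidence,
                    )
                )
    records.sort(key=lambda r: (r.timestamp, r.construct.value))
    return records


def simulate_wearable(
    latent: Dict[Construct, LatentTrajectory],
    config: SimulationConfig,
    seed: int,
    dyad_id: str = "1",
    enrollment_date: Optional[dt.date] = None,
) -> List[WearableDay]:
    """Daily steps / active minutes / sleep hours coupled to latent states."""
    lengths = {len(t) for t in latent.values()}
    if len(lengths) != 1:
        raise ValueError("latent trajectories must share length")
    n_days = lengths.pop()
    start = enrollment_date or config.enrollment_date
    model = config.wearable
    rng = np.random.default_rng(seed)
    days: List[WearableDay] = []
    for day in range(n_days):
        drift = sum(
            w * latent[c].values[day] for c, w in model.step_weights.items()
        )
        noise = rng.normal(0.0, model.step_noise_sd) if model.step_noise_sd else 0.0
        steps = max(0, int(round(model.baseline_steps + drift + noise)))
        sleep_latent = latent[Construct.SLEEP].values[day]
        sleep_noise = (
            rng.normal(0.0, model.sleep_noise_sd) if model.sleep_noise_sd else 0.0
        )
        sleep_hours = max(
            0.0, model.sleep_base_hours + model.sleep_gain_hours * sleep_latent
            + sleep_noise
        )
        # crude intensity split: ~100 steps/min of non-sedentary movement
        active_min = min(600.0, steps / 100.0)
        days.append(
            WearableDay(
                dyad_id=dyad_id,
                date=start + dt.timedelta(days=day),
                steps=steps,
                minutes_by_intensity={
                    "sedentary": 960.0 - min(600.0, active_min),
                    "light": active_min * 0.6,
                    "moderate": active_min * 0.3,
                    "vigorous": active_min * 0.1,
                },
                sleep_hours=float(sleep_hours),
            )
        )
    return days


@dataclass(frozen=True)
class SimulatedDyad:
    dyad_id: str
    latent: Dict[Construct, LatentTrajectory]
    patient_records: List[AssessmentRecord]
    peer_records: List[AssessmentRecord]
    wearable: List[WearableDay]


def simulate_dyad(
    config: SimulationConfig, dyad_id: str, seed: int
) -> SimulatedDyad:
    """Generate one full dyad: latent truth, both report streams, wearables.

    Sub-seeds are derived deterministically from ``seed`` so every stream is
    independently reproducible.
    """
    seeds = np.random.SeedSequence(seed).generate_state(9) % (2**31)
    latent = {
        c: simulate_latent(config, c, int(seeds[i]))
        for i, c in enumerate(Construct)
    }
    prompts = schedule_prompts(
        config.schedule, config.enrollment_date, config.n_days, int(seeds[5])
    )
    patient = simulate_responses(
        prompts, latent, config, Role.PATIENT, int(seeds[6]), dyad_id=dyad_id
    )
    peer = simulate_responses(
        prompts, latent, config, Role.SUPPORT_PERSON, int(seeds[7]), dyad_id=dyad_id
    )
    wearable = simulate_wearable(latent, config, int(seeds[8]), dyad_id=dyad_id)
    return SimulatedDyad(
        dyad_id=dyad_id,
        latent=latent,
        patient_records=patient,
        peer_records=peer,
        wearable=wearable,
    )


def simulate_study(config: SimulationConfig) -> List[SimulatedDyad]:
    """Generate ``config.n_dyads`` dyads, seeded from ``config.seed``."""
    dyad_seeds = np.random.SeedSequence(config.seed).generate_state(
        config.n_dyads
    ) % (2**31)
    return [
        simulate_dyad(config, dyad_id=str(i + 1), seed=int(dyad_seeds[i]))
        for i in range(config.n_dyads)
    ]


def noiseless_config(**overrides) -> SimulationConfig:
    """A convenience configuration with a perfect peer channel and full
    compliance: peer values equal patient values on every prompt day."""
    base = SimulationConfig(
        peer=PeerModel(bias=0.0, noise_sd=0.0, lag_days=0),
        compliance=ComplianceModel(
            p_patient=1.0, p_support=1.0, self_trigger_rate=0.0
        ),
    )
    return replace(base, **overrides) if overrides else base
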