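"""Generate a synthetic study under the default (study-like) conditions.

Seven dyads over 140 days with the deployed prompt schedule, partial
compliance, voluntary self-triggered reports, a biased noisy peer channel,
and coupled wearable streams. Writes the assessment log, wearable log, and
latent ground truth under results/simulated/.
"""

import datetime as dt
from pathlib import Path

import pandas as pd

from peerma.io import write_assessment_log, write_wearable_log
from peerma.simulate import SimulationConfig, simulate_study

OUT = Path("results/simulated")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=SEED)
    dyads = simulate_study(config)
    records = [
        r for d in dyads for r in list(d.patient_records) + list(d.peer_records)
    ]
    write_assessment_log(records, OUT / "assessments.csv")
    write_wearable_log([w for d in dyads for w in d.wearable], OUT / "wearable.csv")
    truth = pd.DataFrame(
        [
            {
                "dyad_id": d.dyad_id,
                "construct": c.value,
                "date": (
                    config.enrollment_date + dt.timedelta(days=day)
                ).isoformat(),
                "latent": v,
            }
            for d in dyads
            for c, trajectory in d.latent.items()
            for day, v in enumerate(trajectory.values)
        ]
    )
    truth.to_csv(OUT / "latent_truth.csv", index=False)
    answered = sum(r.complete for r in records)
    print(
        f"simulated {len(dyads)} dyads x {config.n_days} days (seed {SEED}): "
        f"{len(records)} prompt outcomes, {answered} answered "
        f"({round(100 * answered / len(records))}%)"
    )
    print(f"logs written to {OUT}/")


if __name__ == "__main__":
    main()
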