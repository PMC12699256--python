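"""Prepare the simulated logs: dedup, normalize, align, impute to daily grids.

Reads results/simulated/assessments.csv, builds aligned daily series per
dyad and construct, and writes a tidy per-day export (the data behind the
per-dyad time-series figures) to results/daily_series.csv.
"""

from pathlib import Path

import pandas as pd

from peerma.io import read_assessment_log, read_wearable_log
from peerma.pipeline import export_dyad_series
from peerma.preprocess import build_dyad_streams
from peerma.types import Role

IN = Path("results/simulated")
OUT = Path("results/daily_series.csv")


def main() -> None:
    records = read_assessment_log(IN / "assessments.csv")
    wearable = read_wearable_log(IN / "wearable.csv")
    by_dyad = {}
    for r in records:
        by_dyad.setdefault(r.dyad_id, {}).setdefault(r.role, []).append(r)
    wear_by_dyad = {}
    for w in wearable:
        wear_by_dyad.setdefault(w.dyad_id, []).append(w)
    frames = []
    for dyad_id in sorted(by_dyad, key=int):
        streams = build_dyad_streams(
            by_dyad[dyad_id][Role.PATIENT], by_dyad[dyad_id][Role.SUPPORT_PERSON]
        )
        frames.append(export_dyad_series(streams, wear_by_dyad.get(dyad_id, [])))
        span = (streams.date_range[1] - streams.date_range[0]).days + 1
        print(f"dyad {dyad_id}: aligned range {streams.date_range[0]} .. "
              f"{streams.date_range[1]} ({span} days)")
    pd.concat(frames).to_csv(OUT, index=False)
    print(f"daily series written to {OUT}")


if __name__ == "__main__":
    main()
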