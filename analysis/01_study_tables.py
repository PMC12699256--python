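"""Re-derive the study's summary tables from the packaged printed tables.

Runs the classification, concordance-binning, and accounting layers over
the transcribed per-person means, correlation matrices, and accounting
rows, and writes the resulting tables under results/study_tables/.
"""

from pathlib import Path

from peerma.compliance import study_summary, summaries_from_accounting_table
from peerma.fixtures import load_fixtures
from peerma.pipeline import fixture_tables
from peerma.types import Role

OUT = Path("results/study_tables")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tables = fixture_tables()
    for name, frame in tables.items():
        frame.to_csv(OUT / f"{name}.csv", index=False)

    dyad = tables["dyad_classification"].set_index("strength")
    steps = tables["steps_classification"].set_index("strength")
    positive = dyad.loc[
        ["highly_positive", "moderately_positive", "weakly_positive"], "total_n"
    ].sum()
    print(
        f"dyad correlations: {positive}/35 positive "
        f"({round(100 * positive / 35)}%), "
        f"{dyad.loc['highly_positive', 'total_pct']}% highly positive"
    )
    print(
        f"steps correlations: {steps.loc['highly_negative', 'total_pct']}% "
        "highly negative — more activity tracks less fatigue/depression/pain"
    )

    rows = summaries_from_accounting_table(load_fixtures().table5_accounting)
    _, totals = study_summary(rows)
    print(
        f"accounting: {totals.total_answered[Role.PATIENT]} EMAs and "
        f"{totals.total_answered[Role.SUPPORT_PERSON]} PeerMAs answered; "
        f"patient mean response rate {totals.mean_rate[Role.PATIENT]}%"
    )
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
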