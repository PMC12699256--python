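"""Packaged transcriptions of the study's printed summary tables.

The raw assessment streams of the original study were never deposited, but
its printed summary tables are enough to re-run the downstream layers
(minimal-importance-difference binning, correlation-strength
classification, compliance accounting). The CSVs under ``peerma/data``
transcribe those tables verbatim:

* ``table5_accounting`` — per-participant study days, expected prompt
  counts, answered counts split by trigger, response rates, wearable days;
* ``table6_summaries`` — per person x construct median/mean/SD of the
  min-max-normalized assessments;
* ``table8_steps_correlations`` — 5 patients x 5 constructs Spearman rs
  between self-assessments and daily steps;
* ``table10_dyad_correlations`` — 7 dyads x 5 constructs Spearman rs
  between patient and support-person assessments.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

_DATA_PACKAGE = "peerma.data"


@dataclass(frozen=True)
class FixtureTables:
    table5_accounting: pd.DataFrame
    table6_means: pd.DataFrame
    table8_steps_correlations: pd.DataFrame
    table10_dyad_correlations: pd.DataFrame

    def __post_init__(self) -> None:
        t8, t10 = self.table8_steps_correlations, self.table10_dyad_correlations
        if len(t10) != 35:
            raise ValueError(f"expected 35 dyad correlations, found {len(t10)}")
        if len(t8) != 25:
            raise ValueError(f"expected 25 steps correlations, found {len(t8)}")
        for frame in (t8, t10):
            if not frame["rs"].between(-1.0, 1.0).all():
                raise ValueError("correlation outside [-1, 1] in fixtures")
        if len(self.table6_means) != 7 * 5 * 2:
            raise ValueError("expected 7 dyads x 5 constructs x 2 roles of means")


def _read(name: str) -> pd.DataFrame:
    with resources.files(_DATA_PACKAGE).joinpath(name).open("r") as handle:
        return pd.read_csv(handle)


def load_fixtures() -> FixtureTables:
    """Load the packaged printed-table transcriptions, validated."""
    return FixtureTables(
        table5_accounting=_read("table5_accounting.csv"),
        table6_means=_read("table6_summaries.csv"),
        table8_steps_correlations=_read("table8_steps_correlations.csv"),
        table10_dyad_correlations=_read("table10_dyad_correlations.csv"),
    )
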