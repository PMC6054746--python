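"""Descriptive cohort statistics and exact 2x2 contingency tests.

Case-control exome studies routinely report sex ratios stratified by onset
age and compare carrier proportions between strata with Fisher's exact
test.  This module wraps those small exact computations behind a typed
surface so the rest of the pipeline (and its reports) share one
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact",
    "ratio_summary",
    "cohort_summary",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of non-negative counts; rows are groups, columns outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cell counts must be non-negative integers, got {cells}")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("degenerate table: a row sums to zero")
        if self.a + self.c == 0 or self.b + self.d == 0:
            raise ValueError("degenerate table: a column sums to zero")

    def as_list(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    Uses the minimum-likelihood rule: the p-value sums hypergeometric
    probabilities of all tables (with the observed margins) whose
    probability does not exceed the observed table's.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    res = stats.fisher_exact(table.as_list(), alternative="two-sided")
    return float(res.pvalue)


def ratio_summary(n_female: int, n_male: int) -> str:
    """Format a female-to-male ratio as ``"x:1"`` with one decimal."""
    if n_female < 0 or n_male < 0:
        raise ValueError("counts must be non-negative")
    if n_male == 0:
        return "inf"
    return f"{n_female / n_male:.1f}:1"


def cohort_summary(phenotypes: pd.DataFrame, pediatric_onset_below: float = 18.0) -> pd.DataFrame:
    """Summarise a phenotype table by onset stratum.

    Parameters
    ----------
    phenotypes
        One row per subject with columns ``subject``, ``sex`` ("M"/"F"),
        ``onset_age`` (years), and optionally ``ancestry`` and ``defect``.
    pediatric_onset_below
        Onset-age cutoff (years) separating pediatric from adult onset.

    Returns
    -------
    DataFrame indexed by stratum with male/female counts, totals and the
    formatted female-to-male ratio.
    """
    required = {"subject", "sex", "onset_age"}
    missing = required - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    strata = phenotypes.assign(
        stratum=lambda d: (d["onset_age"] < pediatric_onset_below).map(
            {True: "pediatric", False: "adult"}
        )
    )
    rows = []
    for name, grp in strata.groupby("stratum"):
        n_m = int((grp["sex"] == "M").sum())
        n_f = int((grp["sex"] == "F").sum())
        rows.append(
            {
                "stratum": name,
                "n_male": n_m,
                "n_female": n_f,
                "n_total": len(grp),
                "female_to_male": ratio_summary(n_f, n_m),
            }
        )
    return pd.DataFrame(rows).set_index("stratum")
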