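"""Per-gene and gene-set case-control burden association tests.

The model: pooling cases with a (typically much larger) population-control
cohort, the number of qualifying variants observed in cases, out of the
total observed in both cohorts, follows Binomial(x_case + x_control, rho)
under the null of equal per-subject variant rates, where
rho = n_case / (n_case + n_control).  Enrichment of qualifying variants in
cases is tested with the one-sided (greater) exact binomial tail.

The enrichment rate is reported as the ratio of per-subject frequencies
(x_case / n_case) / (x_control / n_control); this equals the odds of the
binomial proportion estimate against the null rho.

Multiple testing across the per-gene scan is handled by a Bonferroni
threshold (alpha / number of genes tested) and Benjamini-Hochberg FDR.
A batch-effect calibration repeats the pooled test on rare synonymous
variants, a class expected to be neutral, and flags enrichment outside a
configurable band around 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneBurdenTable",
    "BurdenResult",
    "GeneSet",
    "CalibrationReport",
    "binomial_burden_test",
    "genome_wide_scan",
    "bonferroni_threshold",
    "bh_fdr",
    "gene_set_burden",
    "synonymous_calibration",
    "carrier_frequency",
    "attributable_fraction",
    "qq_data",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (e.g. known PAH risk genes)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "members", frozenset(self.members))

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "GeneSet":
        """Read a one-symbol-per-line gene-set file."""
        with open(path) as fh:
            members = {line.strip() for line in fh if line.strip() and not line.startswith("#")}
        return cls(name or str(path), frozenset(members))


@dataclass
class GeneBurdenTable:
    """Per-gene qualifying-variant counts for cases and controls.

    ``counts`` holds one row per gene with columns ``gene``, ``x_case``,
    ``x_control``.  ``n_case`` / ``n_control`` are cohort sizes (subjects).
    ``variant_class_filter`` documents which class of qualifying variants
    the counts reflect (e.g. "rare LGD+D-mis", "rare synonymous").
    """

    counts: pd.DataFrame
    n_case: int
    n_control: int
    variant_class_filter: str = "rare LGD+D-mis"

    def __post_init__(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("cohort sizes must be positive")
        required = {"gene", "x_case", "x_control"}
        missing = required - set(self.counts.columns)
        if missing:
            raise ValueError(f"burden table missing columns: {sorted(missing)}")
        if (self.counts[["x_case", "x_control"]] < 0).any().any():
            raise ValueError("variant counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.counts["gene"])


@dataclass
class BurdenResult:
    """Result of one burden test (a gene or a gene set)."""

    unit: str
    x_case: int
    x_control: int
    n_case: int
    n_control: int
    enrichment_rate: float
    p_value: float
    p_bonferroni: float | None = None
    q_bh: float | None = None
    n_tests: int | None = None
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "unit": self.unit,
            "x_case": self.x_case,
            "x_control": self.x_control,
            "enrichment_rate": self.enrichment_rate,
            "p_value": self.p_value,
            "p_bonferroni": self.p_bonferroni,
            "q_bh": self.q_bh,
        }


def _enrichment_rate(x_case: int, x_control: int, n_case: int, n_control: int) -> float:
    case_freq = x_case / n_case
    if x_control == 0:
        return math.inf if x_case > 0 else math.nan
    return case_freq / (x_control / n_control)


def binomial_burden_test(
    x_case: int,
    x_control: int,
    n_case: int,
    n_control: int,
    unit: str = "",
) -> BurdenResult:
    """One-sided exact binomial burden test for a single unit.

    ``p_value`` is the upper tail P(X >= x_case) for
    X ~ Binomial(x_case + x_control, n_case / (n_case + n_control)).

    Examples
    --------
    >>> r = binomial_burden_test(5, 5, 144, 7509)
    >>> round(r.enrichment_rate)
    52
    """
    for name, v in (("x_case", x_case), ("x_control", x_control)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if n_case <= 0 or n_control <= 0:
        raise ValueError("cohort sizes must be positive")
    total = int(x_case) + int(x_control)
    rho = n_case / (n_case + n_control)
    # sf(k-1) is the exact upper tail P(X >= k); total == 0 gives p = 1.
    p_value = float(stats.binom.sf(x_case - 1, total, rho)) if total > 0 else 1.0
    result = BurdenResult(
        unit=unit,
        x_case=int(x_case),
        x_control=int(x_control),
        n_case=n_case,
        n_control=n_control,
        enrichment_rate=_enrichment_rate(x_case, x_control, n_case, n_control),
        p_value=p_value,
    )
    if x_control == 0 and x_case > 0:
        result.notes.append("x_control=0: enrichment rate infinite")
    return result


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def genome_wide_scan(table: GeneBurdenTable, n_tests: int | None = None) -> pd.DataFrame:
    """Burden test every gene in the table; adjust across the scan.

    Parameters
    ----------
    table
        Per-gene counts and cohort sizes.
    n_tests
        Number of tests used for Bonferroni adjustment.  Defaults to the
        number of genes in the table; pass an override (e.g. 17701) when
        the table is a subset of a larger tested universe.

    Returns
    -------
    DataFrame sorted by p-value with columns ``gene``, ``x_case``,
    ``x_control``, ``enrichment_rate``, ``p_value``, ``p_bonferroni``,
    ``q_bh``.
    """
    df = table.counts.copy()
    m = n_tests if n_tests is not None else len(df)
    rho = table.n_case / (table.n_case + table.n_control)
    total = (df["x_case"] + df["x_control"]).to_numpy()
    p = stats.binom.sf(df["x_case"].to_numpy() - 1, total, rho)
    p = np.where(total > 0, p, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        case_freq = df["x_case"].to_numpy() / table.n_case
        ctrl_freq = df["x_control"].to_numpy() / table.n_control
        enr = case_freq / ctrl_freq
    enr = np.where(
        df["x_control"].to_numpy() == 0,
        np.where(df["x_case"].to_numpy() > 0, np.inf, np.nan),
        enr,
    )
    out = pd.DataFrame(
        {
            "gene": df["gene"],
            "x_case": df["x_case"].astype(int),
            "x_control": df["x_control"].astype(int),
            "enrichment_rate": enr,
            "p_value": p,
            "p_bonferroni": np.minimum(p * m, 1.0),
            "q_bh": bh_fdr(p),
        }
    )
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def gene_set_burden(table: GeneBurdenTable, gene_set: GeneSet) -> BurdenResult:
    """Pooled burden test over a gene set's members.

    Members absent from the table's gene universe contribute zero counts
    and are logged; an empty effective set is an error.
    """
    present = table.counts[table.counts["gene"].isin(gene_set.members)]
    missing = gene_set.members - set(table.counts["gene"])
    if missing:
        logger.info(
            "gene set %s: %d member(s) absent from burden table: %s",
            gene_set.name, len(missing), sorted(missing)[:10],
        )
    if present.empty:
        raise ValueError(f"gene set {gene_set.name!r}: no members present in burden table")
    result = binomial_burden_test(
        int(present["x_case"].sum()),
        int(present["x_control"].sum()),
        table.n_case,
        table.n_control,
        unit=gene_set.name,
    )
    if missing:
        result.notes.append(f"{len(missing)} member(s) absent, counted 0")
    return result


@dataclass
class CalibrationReport:
    """Exome-wide synonymous burden used to gauge case/control batch effects."""

    result: BurdenResult | None
    band: tuple[float, float]
    flagged: bool
    status: str  # "ok", "flagged", "insufficient data"


def synonymous_calibration(
    table: GeneBurdenTable,
    band: tuple[float, float] = (0.9, 1.1),
) -> CalibrationReport:
    """Pooled exome-wide burden test on rare synonymous variants.

    Synonymous variants are expected to be neutral, so a pooled enrichment
    rate far from 1 indicates a platform/batch artifact rather than
    biology.  Enrichment outside ``band`` raises a flag.
    """
    if "synonymous" not in table.variant_class_filter.lower():
        logger.warning(
            "calibration run on variant class %r (expected a synonymous-restricted table)",
            table.variant_class_filter,
        )
    x_case = int(table.counts["x_case"].sum())
    x_control = int(table.counts["x_control"].sum())
    if x_case + x_control == 0:
        return CalibrationReport(None, band, False, "insufficient data")
    result = binomial_burden_test(
        x_case, x_control, table.n_case, table.n_control, unit="synonymous_calibration"
    )
    flagged = not (band[0] <= result.enrichment_rate <= band[1])
    return CalibrationReport(result, band, flagged, "flagged" if flagged else "ok")


def carrier_frequency(n_carriers: int, n_subjects: int) -> float:
    """Carrier frequency as a percentage, 100 * n_carriers / n_subjects."""
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    if not 0 <= n_carriers <= n_subjects:
        raise ValueError("n_carriers must lie in [0, n_subjects]")
    return 100.0 * n_carriers / n_subjects


def attributable_fraction(
    x_case: int, n_case: int, x_control: int, n_control: int
) -> tuple[float, str]:
    """Percent of cases attributable to excess qualifying variants.

    Computed as the difference of per-subject carrier frequencies,
    100 * (x_case/n_case - x_control/n_control).  Returns the value and a
    label recording the formula used, since other definitions (e.g. the
    raw case frequency) are in circulation.
    """
    if min(x_case, x_control) < 0 or n_case <= 0 or n_control <= 0:
        raise ValueError("invalid counts")
    value = 100.0 * (x_case / n_case - x_control / n_control)
    return value, "frequency_difference"


def qq_data(p_values) -> pd.DataFrame:
    """Observed vs expected -log10 p for a quantile-quantile plot.

    Observed p-values are sorted ascending and paired with uniform order
    statistic expectations i / (n + 1).
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("need at least one p-value")
    n = p.size
    expected = np.arange(1, n + 1) / (n + 1)
    with np.errstate(divide="ignore"):
        return pd.DataFrame(
            {
                "expected_neglog10": -np.log10(expected),
                "observed_neglog10": -np.log10(p),
            }
        )
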