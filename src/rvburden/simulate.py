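"""Synthetic cohorts, trios and expression tables for the burden pipeline.

The generators emulate the statistical structure the analysis assumes,
so every stage runs end-to-end without protected data:

* cohort: per-gene qualifying-variant counts are independent Poisson draws
  — control ~ Poisson(n_control * rate), case ~ Poisson(n_case * rate *
  multiplier) — with one or more planted risk genes given an elevated
  multiplier.  Case counts are expanded into annotated variant records
  (consequence, allele frequencies, REVEL) whose classification
  reproduces the intended qualifying status.  Synonymous variants are
  generated alongside, with an optional batch-shift multiplier on the
  control synonymous rate to emulate platform artifacts.
* trios: de novo substitutions are placed on a coding sequence with
  probability proportional to a trinucleotide rate table, two transmitted
  genomes per trio, parents homozygous reference at event sites.
* expression: two tissues with independent background quantiles and a
  signal set pushed into the top quartile of both.

Defaults mirror the study scale this package models: 144 cases of
European ancestry against 7509 population controls across 17,701 genes,
with a planted risk gene whose control frequency is 5/7509 and whose
case rate is elevated 52-fold.  All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .denovo import BASES, MappableCodingSequence, TrinucRateTable
from .qc import Genotype

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticTrioSpec",
    "CohortData",
    "generate_cohort",
    "build_burden_counts",
    "generate_trios",
    "generate_expression",
    "signal_strength_for_fraction",
    "generate_qc_sites",
    "generate_phenotypes",
    "DEFAULT_PLANTED_GENE",
]

DEFAULT_PLANTED_GENE = "RISK1"

# Default per-gene per-subject rate of rare deleterious qualifying variants,
# set so a null gene shows ~5 carriers among 7509 controls (the regime of the
# planted risk gene).  Genome-wide this yields ~12 qualifying variants per
# subject, a realistic exome-wide burden of rare LGD + damaging missense calls.
DEFAULT_BASELINE_RATE = 5 / 7509
# Synonymous variants are a few-fold more common than deleterious ones.
DEFAULT_SYNONYMOUS_RATE = 1.5e-3

_LGD_CONSEQUENCES = ("stopgain", "frameshift_indel", "canonical_splice")


@dataclass
class SyntheticCohortSpec:
    """Study-condition parameters for the synthetic case-control cohort."""

    n_case: int = 144
    n_control: int = 7509
    n_genes: int = 17_701
    baseline_rate: float = DEFAULT_BASELINE_RATE
    planted_genes: Mapping[str, float] = field(
        default_factory=lambda: {DEFAULT_PLANTED_GENE: 52.0}
    )
    synonymous_rate: float = DEFAULT_SYNONYMOUS_RATE
    batch_shift: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_case, self.n_control, self.n_genes) <= 0:
            raise ValueError("cohort sizes and gene count must be positive")
        if self.baseline_rate <= 0 or self.synonymous_rate <= 0:
            raise ValueError("rates must be positive")
        if any(m < 1 for m in self.planted_genes.values()):
            raise ValueError("planted multipliers must be >= 1")

    def gene_names(self) -> list[str]:
        planted = list(self.planted_genes)
        n_null = self.n_genes - len(planted)
        if n_null < 0:
            raise ValueError("more planted genes than genes")
        return planted + [f"GENE{i:05d}" for i in range(n_null)]


@dataclass
class CohortData:
    """Output bundle of :func:`generate_cohort`."""

    case_variants: pd.DataFrame  # one row per variant observation in a case
    control_counts: pd.DataFrame  # gene, x_control, x_control_synonymous
    spec: SyntheticCohortSpec

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.case_variants.to_csv(outdir / "case_variants.tsv", sep="\t", index=False)
        self.control_counts.to_csv(outdir / "control_counts.tsv", sep="\t", index=False)


def _expand_case_records(
    rng: np.random.Generator,
    genes: np.ndarray,
    counts: np.ndarray,
    n_case: int,
    synonymous: bool,
) -> pd.DataFrame:
    """Turn per-gene case counts into annotated variant records."""
    total = int(counts.sum())
    gene_col = np.repeat(genes, counts)
    sample_idx = rng.integers(0, n_case, size=total)
    if synonymous:
        consequence = np.full(total, "synonymous", dtype=object)
        revel = np.full(total, np.nan)
    else:
        # ~half LGD, half damaging missense, echoing observed class mixes
        is_mis = rng.random(total) < 0.5
        consequence = np.where(
            is_mis, "missense", rng.choice(_LGD_CONSEQUENCES, size=total)
        ).astype(object)
        revel = np.where(is_mis, rng.uniform(0.55, 1.0, size=total), np.nan)
    ref = rng.choice(list(BASES), size=total)
    alt_offset = rng.integers(1, 4, size=total)
    base_idx = np.searchsorted(np.array(BASES), ref)
    alt = np.array(BASES)[(base_idx + alt_offset) % 4]
    return pd.DataFrame(
        {
            "sample_id": [f"CASE{int(i):04d}" for i in sample_idx],
            "gene": gene_col,
            "chrom": "1",
            "pos": rng.integers(1, 250_000_000, size=total),
            "ref": ref,
            "alt": alt,
            "consequence": consequence,
            "af_exac": np.nan,  # absent from references: rare
            "af_gnomad_wes": np.nan,
            "revel": revel,
            "cadd": np.round(rng.uniform(15, 40, size=total), 1),
        }
    )


def generate_cohort(spec: SyntheticCohortSpec) -> CohortData:
    """Draw a full synthetic case-control cohort under ``spec``.

    Per-gene counts are independent Poisson; the annotation fields of the
    case records are constructed so that rarity/deleteriousness
    classification recovers exactly the generated qualifying counts.
    """
    rng = np.random.default_rng(spec.seed)
    genes = np.array(spec.gene_names(), dtype=object)
    mult = np.ones(spec.n_genes)
    for i, g in enumerate(genes[: len(spec.planted_genes)]):
        mult[i] = spec.planted_genes[g]

    lam_control = spec.n_control * spec.baseline_rate
    lam_case = spec.n_case * spec.baseline_rate * mult
    x_control = rng.poisson(lam_control, size=spec.n_genes)
    x_case = rng.poisson(lam_case)

    lam_syn_control = spec.n_control * spec.synonymous_rate * spec.batch_shift
    lam_syn_case = spec.n_case * spec.synonymous_rate
    x_control_syn = rng.poisson(lam_syn_control, size=spec.n_genes)
    x_case_syn = rng.poisson(lam_syn_case, size=spec.n_genes)

    case_del = _expand_case_records(rng, genes, x_case, spec.n_case, synonymous=False)
    case_syn = _expand_case_records(rng, genes, x_case_syn, spec.n_case, synonymous=True)
    case_variants = (
        pd.concat([case_del, case_syn], ignore_index=True)
        .sample(frac=1.0, random_state=int(rng.integers(2**31)))
        .reset_index(drop=True)
    )
    control_counts = pd.DataFrame(
        {"gene": genes, "x_control": x_control, "x_control_synonymous": x_control_syn}
    )
    return CohortData(case_variants, control_counts, spec)


def build_burden_counts(
    case_variants: pd.DataFrame,
    control_counts: pd.DataFrame,
    variant_class: str = "deleterious",
) -> pd.DataFrame:
    """Per-gene case counts (via classification) joined to control counts.

    ``variant_class`` is "deleterious" (rare LGD + D-mis) or "synonymous"
    (rare synonymous).  Returns columns gene, x_case, x_control over the
    full control gene universe.
    """
    from .classify import classify_table

    classified = classify_table(case_variants)
    rare = classified[classified["rare"]]
    if variant_class == "deleterious":
        qualifying = rare[rare["dclass"].isin(["LGD", "D_mis"])]
        ctrl_col = "x_control"
    elif variant_class == "synonymous":
        qualifying = rare[rare["dclass"] == "synonymous"]
        ctrl_col = "x_control_synonymous"
    else:
        raise ValueError(f"unknown variant_class {variant_class!r}")
    case_counts = qualifying.groupby("gene").size()
    out = control_counts[["gene"]].copy()
    out["x_case"] = out["gene"].map(case_counts).fillna(0).astype(int)
    out["x_control"] = control_counts[ctrl_col].astype(int)
    return out


@dataclass
class SyntheticTrioSpec:
    """Parameters for the synthetic trio de novo generator."""

    n_trios: int = 60
    rate_table: Optional[TrinucRateTable] = None
    cds: Sequence[MappableCodingSequence] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trios <= 0:
            raise ValueError("n_trios must be positive")


def generate_trios(spec: SyntheticTrioSpec) -> pd.DataFrame:
    """Place de novo substitutions on the coding sequence by mutation rate.

    The total event count is Poisson with mean m0(all) = 2 * n_trios *
    (summed per-site rates); each event lands on a (position, alt) drawn
    proportional to its rate, on a uniformly chosen trio.  Parents are
    homozygous reference at every event site.

    Returns one row per event: trio_id, gene, cds_pos (0-based), ref, alt,
    variant_class, child/mother/father genotype strings.
    """
    if spec.rate_table is None or not spec.cds:
        raise ValueError("trio spec needs a rate table and coding sequence")
    rng = np.random.default_rng(spec.seed)
    sites: list[tuple[str, int, str, str, str, float]] = []
    for seq in spec.cds:
        for pos in range(len(seq.sequence)):
            if not seq.mappable[pos]:
                continue
            ctx = seq.context(pos)
            if ctx is None:
                continue
            five, ref, three = ctx
            for alt in BASES:
                if alt == ref:
                    continue
                cls = seq.annotation.get((pos, alt))
                if cls is None:
                    continue
                r = spec.rate_table.rate(five, ref, three, alt)
                if r > 0:
                    sites.append((seq.gene, pos, ref, alt, cls, r))
    columns = [
        "trio_id", "gene", "cds_pos", "ref", "alt", "variant_class",
        "child", "mother", "father",
    ]
    if not sites:
        return pd.DataFrame(columns=columns)
    rates = np.array([s[5] for s in sites])
    m0_all = 2.0 * spec.n_trios * rates.sum()
    n_events = rng.poisson(m0_all)
    if n_events == 0:
        return pd.DataFrame(columns=columns)
    picks = rng.choice(len(sites), size=n_events, p=rates / rates.sum())
    trios = rng.integers(0, spec.n_trios, size=n_events)
    rows = []
    for trio, si in zip(trios, picks):
        gene, pos, ref, alt, cls, _ = sites[si]
        rows.append(
            {
                "trio_id": f"TRIO{int(trio):03d}",
                "gene": gene,
                "cds_pos": pos,
                "ref": ref,
                "alt": alt,
                "variant_class": cls,
                "child": Genotype.HET.value,
                "mother": Genotype.HOM_REF.value,
                "father": Genotype.HOM_REF.value,
            }
        )
    return pd.DataFrame(rows, columns=columns)


def signal_strength_for_fraction(target_fraction: float) -> float:
    """Signal strength giving an expected double-top fraction.

    With strength s, a signal gene is boosted into the top quartile of
    both tissues with probability s and otherwise behaves as background
    (double-top probability 1/16), so the expected fraction is
    s + (1 - s)/16.
    """
    base = 1.0 / 16.0
    if not base <= target_fraction <= 1:
        raise ValueError(f"target fraction must lie in [{base}, 1]")
    return (target_fraction - base) / (1 - base)


def generate_expression(
    n_genes: int,
    signal_set: Sequence[str] = (),
    signal_strength: float = 0.0,
    seed: int = 0,
    gene_names: Optional[Sequence[str]] = None,
) -> tuple[pd.Series, pd.Series]:
    """Two per-gene expression tables with an optional planted signal.

    Background genes get independent Uniform(0, 1) expression values per
    tissue (so independent quantiles).  Each signal gene is boosted with
    probability ``signal_strength``: boosted genes draw both values from
    Uniform(1, 2), strictly above the background range, which guarantees
    top-quartile rank in both tissues whenever boosted genes are fewer
    than a quarter of the table.  The number of boosted genes is fixed at
    round(strength * |signal|) rather than binomial, for tighter control
    of the planted overlap.
    """
    if not 0 <= signal_strength <= 1:
        raise ValueError("signal_strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if gene_names is None:
        gene_names = [f"GENE{i:05d}" for i in range(n_genes)]
    if len(gene_names) != n_genes:
        raise ValueError("gene_names length mismatch")
    index = pd.Index(gene_names, name="gene")
    missing = set(signal_set) - set(gene_names)
    if missing:
        raise ValueError(f"signal genes not in universe: {sorted(missing)[:5]}")
    a = rng.random(n_genes)
    b = rng.random(n_genes)
    signal_set = list(signal_set)
    if signal_set and signal_strength > 0:
        n_boost = int(round(signal_strength * len(signal_set)))
        boosted = rng.choice(signal_set, size=n_boost, replace=False)
        loc = index.get_indexer(boosted)
        a[loc] = rng.uniform(1.0, 2.0, size=n_boost)
        b[loc] = rng.uniform(1.0, 2.0, size=n_boost)
    return pd.Series(a, index=index, name="tissue_a"), pd.Series(b, index=index, name="tissue_b")


def generate_qc_sites(
    n_sites: int = 50,
    n_samples: int = 6,
    fail_fraction: float = 0.3,
    seed: int = 0,
    chrom: str = "1",
    region_end: int = 1_000_000,
):
    """Genotype-level variant sites exercising every QC filter.

    Roughly ``fail_fraction`` of sites are given exactly one site-level
    defect (missingness, mappability, VQSR tranche, or non-PASS filter);
    clean sites may still contain genotype calls failing depth, allele
    balance or genotype quality.  Returns (sites, regions, expected_fail
    count) where regions covers [0, region_end) of ``chrom``.
    """
    from .qc import CaptureRegions, GenotypeCall, SiteQC, VariantSite

    rng = np.random.default_rng(seed)
    defects = ["missingness", "mappability", "vqsr", "filter_status", "outside_capture"]
    sites = []
    n_fail = 0
    for i in range(n_sites):
        qc_kwargs = dict(missingness=0.0, mappability=1.0, vqsr_tranche=99.8, filter_status="PASS")
        pos = int(rng.integers(1, region_end))
        if rng.random() < fail_fraction:
            defect = defects[int(rng.integers(len(defects)))]
            if defect == "missingness":
                qc_kwargs["missingness"] = 0.2
            elif defect == "mappability":
                qc_kwargs["mappability"] = 0.5
            elif defect == "vqsr":
                qc_kwargs["vqsr_tranche"] = 99.0
            elif defect == "filter_status":
                qc_kwargs["filter_status"] = "VQSRTrancheSNP99.60to99.80"
            else:
                pos = region_end + 1000 + i
            n_fail += 1
        calls = []
        for s in range(n_samples):
            gt = Genotype.HET if rng.random() < 0.3 else Genotype.HOM_REF
            bad = rng.random() < 0.2
            if gt is Genotype.HET:
                calls.append(
                    GenotypeCall(
                        sample_id=f"S{s}",
                        genotype=gt,
                        depth=5 if bad else int(rng.integers(15, 80)),
                        allele_balance=0.1 if bad else float(rng.uniform(0.3, 0.7)),
                        genotype_quality=float(rng.integers(40, 99)),
                    )
                )
            else:
                calls.append(
                    GenotypeCall(
                        sample_id=f"S{s}",
                        genotype=gt,
                        depth=int(rng.integers(15, 80)),
                        genotype_quality=float(rng.integers(40, 99)),
                    )
                )
        ref, alt = ("A", "G") if rng.random() < 0.5 else ("C", "T")
        sites.append(VariantSite(chrom, pos, ref, alt, SiteQC(**qc_kwargs), tuple(calls)))
    regions = CaptureRegions([(chrom, 0, region_end)])
    return sites, regions, n_fail


def generate_phenotypes(
    n_pediatric: int = 144,
    n_adult: int = 112,
    female_fraction_pediatric: float = 91 / 144,
    female_fraction_adult: float = 88 / 112,
    seed: int = 0,
) -> pd.DataFrame:
    """Subject phenotype table with onset-stratified sex composition.

    Defaults reproduce the pediatric/adult sex composition of the modelled
    cohort exactly (deterministic counts, randomised order).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for stratum, n, f_frac, ages in (
        ("pediatric", n_pediatric, female_fraction_pediatric, (0, 18)),
        ("adult", n_adult, female_fraction_adult, (18, 70)),
    ):
        n_f = int(round(n * f_frac))
        sexes = ["F"] * n_f + ["M"] * (n - n_f)
        for sex in sexes:
            rows.append(
                {
                    "subject": f"P{len(rows):04d}",
                    "sex": sex,
                    "onset_age": float(rng.uniform(*ages)),
                    "ancestry": "European",
                    "defect": "ASD",
                }
            )
    df = pd.DataFrame(rows)
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
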