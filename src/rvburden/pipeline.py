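"""End-to-end orchestration: qc -> classify -> burden -> de novo -> expression.

The pipeline consumes either prepared inputs (VCF / TSV / gene-set files)
or, when ``simulate`` is enabled, a synthetic cohort drawn at run time.
Every stage writes plain-text TSV outputs plus a JSON metadata sidecar
recording the thresholds, seed and cohort sizes used, so a run is fully
reproducible from its output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden import (
    GeneBurdenTable,
    GeneSet,
    bonferroni_threshold,
    genome_wide_scan,
    gene_set_burden,
    qq_data,
    synonymous_calibration,
)
from .classify import RARE_AF_CUTOFF, REVEL_CUTOFF
from .denovo import TrinucRateTable, annotate_cds, expected_count, poisson_enrichment
from .expression import TOP_QUARTILE, ExpressionRankTable, permutation_test
from .simulate import (
    SyntheticCohortSpec,
    SyntheticTrioSpec,
    build_burden_counts,
    generate_cohort,
    generate_expression,
    generate_trios,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A named stage failure."""


@dataclass
class PipelineConfig:
    """Thresholds, cohort sizes, stage toggles and I/O paths.

    Threshold defaults are the analysis' canonical values: rare means
    population AF < 0.01%, damaging missense means REVEL > 0.5, the
    genome-wide scan uses alpha = 0.05 with a Bonferroni denominator of
    the number of genes tested, and the expression overlap uses the 75th
    percentile.
    """

    out_dir: str = "rvburden_out"
    seed: int = 0
    # thresholds
    af_cutoff: float = RARE_AF_CUTOFF
    revel_cutoff: float = REVEL_CUTOFF
    alpha: float = 0.05
    quartile: float = TOP_QUARTILE
    n_tests_override: Optional[int] = None
    # cohort
    n_case: int = 144
    n_control: int = 7509
    n_genes: int = 17_701
    # stage toggles
    run_burden: bool = True
    run_calibration: bool = True
    run_denovo: bool = True
    run_expression: bool = True
    # synthetic mode + scale knobs
    simulate: bool = True
    n_trios: int = 60
    n_perm: int = 100_000
    expression_signal_size: int = 149
    expression_signal_strength: float = 0.0
    # prepared-input paths (used when simulate is false)
    case_variants_tsv: Optional[str] = None
    control_counts_tsv: Optional[str] = None
    gene_set_files: list[str] = field(default_factory=list)
    expr_a_tsv: Optional[str] = None
    expr_b_tsv: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 < self.af_cutoff < 1:
            raise PipelineError("af_cutoff must lie in (0, 1)")
        if not 0 <= self.revel_cutoff <= 1:
            raise PipelineError("revel_cutoff must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise PipelineError("alpha must lie in (0, 1)")
        if not 0 < self.quartile < 1:
            raise PipelineError("quartile must lie in (0, 1)")
        if not self.simulate:
            for name in ("case_variants_tsv", "control_counts_tsv"):
                if self.run_burden and getattr(self, name) is None:
                    raise PipelineError(f"missing input: {name} (simulate is off)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order and write the report bundle.

    Returns a dict with the in-memory results (scan DataFrame, calibration
    report, de novo table, expression result) keyed by stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    rng = np.random.default_rng(config.seed)

    case_variants = control_counts = None
    if config.simulate:
        spec = SyntheticCohortSpec(
            n_case=config.n_case,
            n_control=config.n_control,
            n_genes=config.n_genes,
            seed=int(rng.integers(2**31)),
        )
        cohort = generate_cohort(spec)
        case_variants, control_counts = cohort.case_variants, cohort.control_counts
    elif config.run_burden or config.run_calibration:
        case_variants = pd.read_csv(config.case_variants_tsv, sep="\t")
        control_counts = pd.read_csv(config.control_counts_tsv, sep="\t")

    if config.run_burden:
        counts = build_burden_counts(case_variants, control_counts, "deleterious")
        table = GeneBurdenTable(counts, config.n_case, config.n_control)
        scan = genome_wide_scan(table, n_tests=config.n_tests_override)
        scan.to_csv(out / "burden_scan.tsv", sep="\t", index=False)
        qq = qq_data(scan["p_value"])
        qq.to_csv(out / "qq_data.tsv", sep="\t", index=False)
        report["burden"] = scan
        report["bonferroni_threshold"] = bonferroni_threshold(
            config.n_tests_override or len(scan), config.alpha
        )
        sets = {}
        for path in config.gene_set_files:
            gs = GeneSet.from_file(path, Path(path).stem)
            sets[gs.name] = gene_set_burden(table, gs)
        if sets:
            pd.DataFrame([r.as_dict() for r in sets.values()]).to_csv(
                out / "gene_set_burden.tsv", sep="\t", index=False
            )
            report["gene_sets"] = sets

    if config.run_calibration and control_counts is not None:
        if "x_control_synonymous" in control_counts.columns:
            syn_counts = build_burden_counts(case_variants, control_counts, "synonymous")
            syn_table = GeneBurdenTable(
                syn_counts, config.n_case, config.n_control,
                variant_class_filter="rare synonymous",
            )
            calib = synonymous_calibration(syn_table)
            report["calibration"] = calib
            with open(out / "calibration.json", "w") as fh:
                json.dump(
                    {
                        "status": calib.status,
                        "band": list(calib.band),
                        "enrichment": calib.result.enrichment_rate if calib.result else None,
                        "p_value": calib.result.p_value if calib.result else None,
                    },
                    fh,
                    indent=2,
                )
        else:
            logger.warning("calibration skipped: no synonymous control counts")

    if config.run_denovo:
        # compact synthetic coding model: a handful of genes, ~1.2 kb CDS each
        cds_rng = np.random.default_rng(int(rng.integers(2**31)))
        seqs = []
        for gi in range(5):
            length = 1200
            seq = "ATG" + "".join(cds_rng.choice(list("ACGT"), size=length - 6)) + "TAA"
            seqs.append(annotate_cds(f"DNGENE{gi}", seq, flank5="A", flank3="A"))
        rates = TrinucRateTable.uniform(1e-6)
        trio_spec = SyntheticTrioSpec(
            n_trios=config.n_trios, rate_table=rates, cds=seqs,
            seed=int(rng.integers(2**31)),
        )
        events = generate_trios(trio_spec)
        rows = []
        for cls in ("synonymous", "missense", "LGD", "all"):
            m0 = expected_count(rates, seqs, config.n_trios, cls)
            m1 = len(events) if cls == "all" else int((events["variant_class"] == cls).sum())
            r = poisson_enrichment(m1, m0, cls)
            rows.append(
                {"variant_class": cls, "m1": r.m1, "m0": r.m0,
                 "enrichment": r.enrichment, "p_value": r.p_value}
            )
        denovo_table = pd.DataFrame(rows)
        denovo_table.to_csv(out / "denovo_enrichment.tsv", sep="\t", index=False)
        report["denovo"] = denovo_table

    if config.run_expression:
        if config.simulate:
            genes = [f"GENE{i:05d}" for i in range(2000)]
            focal_genes = genes[: config.expression_signal_size]
            a, b = generate_expression(
                len(genes),
                signal_set=focal_genes,
                signal_strength=config.expression_signal_strength,
                seed=int(rng.integers(2**31)),
                gene_names=genes,
            )
            expr = ExpressionRankTable(a, b)
            focal = GeneSet("focal", frozenset(focal_genes))
            background = GeneSet("background", frozenset(genes))
        else:
            if not (config.expr_a_tsv and config.expr_b_tsv and len(config.gene_set_files) >= 2):
                raise PipelineError(
                    "expression stage needs expr_a_tsv, expr_b_tsv and focal+background gene sets"
                )
            expr = ExpressionRankTable.from_tsv(config.expr_a_tsv, config.expr_b_tsv)
            focal = GeneSet.from_file(config.gene_set_files[0], "focal")
            background = GeneSet.from_file(config.gene_set_files[1], "background")
        res = permutation_test(
            focal, background, expr,
            n_perm=config.n_perm,
            seed=int(rng.integers(2**31)),
            threshold=config.quartile,
        )
        res.histogram().to_csv(out / "expression_null_histogram.tsv", sep="\t", index=False)
        report["expression"] = res

    meta = {
        "package_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "af_cutoff": config.af_cutoff,
            "revel_cutoff": config.revel_cutoff,
            "alpha": config.alpha,
            "quartile": config.quartile,
            "n_tests": config.n_tests_override or config.n_genes,
        },
        "cohort": {"n_case": config.n_case, "n_control": config.n_control},
        "stages_run": [
            k for k, on in (
                ("burden", config.run_burden),
                ("calibration", config.run_calibration),
                ("denovo", config.run_denovo),
                ("expression", config.run_expression),
            ) if on
        ],
    }
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    report["metadata"] = meta
    return report
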