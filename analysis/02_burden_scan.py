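#!/usr/bin/env python
"""Genome-wide burden scan on the simulated cohort.

Classifies the case variants, counts rare deleterious (LGD + D-mis)
qualifying variants per gene, runs the one-sided binomial burden test in
every gene against the control counts, applies Bonferroni and
Benjamini-Hochberg adjustment, checks the synonymous batch-effect
calibration, and writes the ranked results plus QQ data under
results/burden/.

Run 01_simulate_cohort.py first.
"""

from pathlib import Path

import pandas as pd

from rvburden.burden import (
    GeneBurdenTable,
    bonferroni_threshold,
    genome_wide_scan,
    qq_data,
    synonymous_calibration,
)
from rvburden.simulate import build_burden_counts

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cases = pd.read_csv(ROOT / "cohort" / "case_variants.tsv", sep="\t")
    controls = pd.read_csv(ROOT / "cohort" / "control_counts.tsv", sep="\t")
    out = ROOT / "burden"
    out.mkdir(parents=True, exist_ok=True)

    counts = build_burden_counts(cases, controls, "deleterious")
    table = GeneBurdenTable(counts, n_case=144, n_control=7509)
    scan = genome_wide_scan(table)
    scan.head(1000).to_csv(out / "burden_scan_top1000.tsv", sep="\t", index=False)
    qq = qq_data(scan["p_value"])
    qq.iloc[:: max(1, len(qq) // 2000)].to_csv(out / "qq_data.tsv", sep="\t", index=False)

    threshold = bonferroni_threshold(len(scan), 0.05)
    significant = scan[scan["p_value"] < threshold]
    print(f"scanned {len(scan)} genes; Bonferroni threshold {threshold:.2g}")
    print("top 5 associations:")
    print(scan.head(5).to_string(index=False))
    print(f"genome-wide significant genes: {list(significant['gene'])}")

    syn = build_burden_counts(cases, controls, "synonymous")
    calib = synonymous_calibration(
        GeneBurdenTable(syn, 144, 7509, variant_class_filter="rare synonymous")
    )
    print(
        f"synonymous calibration: enrichment {calib.result.enrichment_rate:.3f}, "
        f"p {calib.result.p_value:.2g}, status {calib.status}"
    )


if __name__ == "__main__":
    main()
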