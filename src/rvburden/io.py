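"""Readers and writers for the pipeline's on-disk formats.

Variant sites round-trip through VCF (read with pysam; site QC carried in
INFO keys ``MISS``, ``MAPPABILITY``, ``VQSR`` and per-genotype QC in
``GT``/``DP``/``AD``/``GQ``), capture regions come from BED, and tabular
data (annotations, counts, results) through plain TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .qc import Genotype, GenotypeCall, SiteQC, VariantSite

__all__ = ["read_vcf", "write_vcf", "read_trio_vcf", "write_trio_vcf"]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=MISS,Number=1,Type=Float,Description="Genotype missingness at site">
##INFO=<ID=MAPPABILITY,Number=1,Type=Float,Description="Mappability of 150bp fragments">
##INFO=<ID=VQSR,Number=1,Type=Float,Description="VQSR tranche sensitivity">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""

_GT_STR = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def _format_call(call: GenotypeCall) -> str:
    if call.genotype is Genotype.MISSING:
        return "./.:.:.:."
    dp = call.depth if call.depth is not None else "."
    gq = int(call.genotype_quality) if call.genotype_quality is not None else "."
    if call.depth is not None and call.allele_balance is not None:
        alt_reads = int(round(call.allele_balance * call.depth))
        ad = f"{call.depth - alt_reads},{alt_reads}"
    elif call.genotype is Genotype.HOM_REF and call.depth is not None:
        ad = f"{call.depth},0"
    elif call.genotype is Genotype.HOM_ALT and call.depth is not None:
        ad = f"0,{call.depth}"
    else:
        ad = "."
    return f"{_GT_STR[call.genotype]}:{dp}:{ad}:{gq}"


def write_vcf(sites: Sequence[VariantSite], path) -> None:
    """Write variant sites (with QC annotations) to an uncompressed VCF."""
    samples: list[str] = []
    for site in sites:
        for call in site.calls:
            if call.sample_id not in samples:
                samples.append(call.sample_id)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in sorted({s.chrom for s in sites}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT")
        fh.write("\t" + "\t".join(samples) + "\n" if samples else "\n")
        for site in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            qc = site.site_qc
            info = f"MISS={qc.missingness:g};MAPPABILITY={qc.mappability:g};VQSR={qc.vqsr_tranche:g}"
            by_sample = {c.sample_id: c for c in site.calls}
            fields = [
                site.chrom, str(site.pos), ".", site.ref, site.alt, ".",
                qc.filter_status, info, "GT:DP:AD:GQ",
            ]
            for s in samples:
                call = by_sample.get(s, GenotypeCall(s, Genotype.MISSING))
                fields.append(_format_call(call))
            fh.write("\t".join(fields) + "\n")


def _parse_genotype(gt: tuple) -> Genotype:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return Genotype.MISSING
    n_alt = sum(1 for a in alleles if a > 0)
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt == len(alleles):
        return Genotype.HOM_ALT
    return Genotype.HET


def read_vcf(path) -> list[VariantSite]:
    """Read a VCF into variant sites, decomposing multi-allelic records.

    Site QC comes from INFO keys ``MISS``, ``MAPPABILITY`` and ``VQSR``
    (a VQSR tranche may instead be parsed from a FILTER string such as
    ``VQSRTrancheSNP99.60to99.80``; a plain PASS counts as tranche 99.6+).
    Missing QC INFO keys default to clean values so externally produced
    VCFs remain readable.
    """
    sites: list[VariantSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            filters = list(rec.filter.keys()) or ["PASS"]
            filter_status = "PASS" if filters == ["PASS"] else ";".join(filters)
            vqsr = rec.info.get("VQSR")
            if vqsr is None:
                vqsr = _tranche_from_filter(filter_status)
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                calls = []
                n_missing = 0
                for s in sample_names:
                    sample = rec.samples[s]
                    gt_raw = sample.get("GT") or (None,)
                    # restrict to this alt: other alts count as ref
                    gt_this = tuple(
                        None if a is None else (1 if a == alt_index else 0) for a in gt_raw
                    )
                    genotype = _parse_genotype(gt_this)
                    if genotype is Genotype.MISSING:
                        n_missing += 1
                        calls.append(GenotypeCall(s, Genotype.MISSING))
                        continue
                    dp = sample.get("DP")
                    gq = sample.get("GQ")
                    ad = sample.get("AD")
                    ab = None
                    if genotype is Genotype.HET and ad is not None and dp:
                        alt_reads = ad[alt_index] if len(ad) > alt_index else 0
                        denom = sum(a for a in ad if a is not None)
                        ab = (alt_reads or 0) / denom if denom else 0.0
                    calls.append(
                        GenotypeCall(
                            sample_id=s,
                            genotype=genotype,
                            depth=dp,
                            allele_balance=ab,
                            genotype_quality=float(gq) if gq is not None else None,
                        )
                    )
                miss = rec.info.get("MISS")
                if miss is None:
                    miss = n_missing / len(sample_names) if sample_names else 0.0
                sites.append(
                    VariantSite(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        site_qc=SiteQC(
                            missingness=float(miss),
                            mappability=float(rec.info.get("MAPPABILITY", 1.0)),
                            vqsr_tranche=float(vqsr),
                            filter_status=filter_status,
                        ),
                        calls=tuple(calls),
                    )
                )
    return sites


def _tranche_from_filter(filter_status: str) -> float:
    """Tranche sensitivity implied by a FILTER string.

    PASS means the call sits in the most confident tranche (>= 99.6 here);
    a ``VQSRTrancheSNP99.60to99.80``-style label yields its lower bound.
    """
    if filter_status == "PASS":
        return 99.6
    if "VQSRTranche" in filter_status:
        import re

        m = re.search(r"(\d+\.?\d*)to(\d+\.?\d*)", filter_status)
        if m:
            return float(m.group(1))
    return 0.0


def write_trio_vcf(events: pd.DataFrame, path) -> None:
    """Write generated trio de novo events as a VCF.

    Each trio contributes three sample columns (``<trio>_C``, ``_M``,
    ``_F``); positions are 1-based CDS coordinates on a per-gene contig.
    """
    trios = sorted(events["trio_id"].unique()) if len(events) else []
    samples = [f"{t}_{m}" for t in trios for m in ("C", "M", "F")]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=VCLASS,Number=1,Type=String,Description="Consequence class">\n')
        for gene in sorted(events["gene"].unique()) if len(events) else []:
            fh.write(f"##contig=<ID={gene}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT")
        fh.write("\t" + "\t".join(samples) + "\n" if samples else "\n")
        gt_map = {g.value: s for g, s in _GT_STR.items()}
        for row in events.sort_values(["gene", "cds_pos"]).itertuples(index=False):
            gts = []
            for t in trios:
                if t == row.trio_id:
                    gts += [gt_map[row.child], gt_map[row.mother], gt_map[row.father]]
                else:
                    gts += ["0/0", "0/0", "0/0"]
            fields = [
                row.gene, str(row.cds_pos + 1), ".", row.ref, row.alt, ".", "PASS",
                f"GENE={row.gene};VCLASS={row.variant_class}", "GT",
            ] + gts
            fh.write("\t".join(fields) + "\n")


def read_trio_vcf(path) -> pd.DataFrame:
    """Inverse of :func:`write_trio_vcf`: one row per trio carrying an alt."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        trios = sorted({s.rsplit("_", 1)[0] for s in samples})
        for rec in vcf:
            for trio in trios:
                gts = {
                    member: _parse_genotype(rec.samples[f"{trio}_{member}"].get("GT") or (None,))
                    for member in ("C", "M", "F")
                }
                if gts["C"] in (Genotype.HET, Genotype.HOM_ALT) or any(
                    g is not Genotype.HOM_REF for g in gts.values()
                ):
                    rows.append(
                        {
                            "trio_id": trio,
                            "gene": rec.info.get("GENE", rec.chrom),
                            "cds_pos": rec.pos - 1,
                            "ref": rec.ref,
                            "alt": rec.alts[0],
                            "variant_class": rec.info.get("VCLASS", "unknown"),
                            "child": gts["C"].value,
                            "mother": gts["M"].value,
                            "father": gts["F"].value,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "trio_id", "gene", "cds_pos", "ref", "alt", "variant_class",
            "child", "mother", "father",
        ],
    )
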