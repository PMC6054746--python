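"""Heuristic genotype- and site-level QC filters for exome variant calls.

Filters follow the common hard-filter recipe for case cohorts jointly
analysed with population references: per-genotype read depth, allele
balance and genotype quality cutoffs; per-site missingness, mappability,
VQSR tranche sensitivity and FILTER status; and restriction to the capture
(protein-coding) regions.

Boundary semantics are literal: a genotype is excluded when depth <= 8,
allele balance <= 0.20 or genotype quality < 30; a site is excluded when
missingness > 0.10, mappability < 1, VQSR tranche < 99.6, FILTER is not
"PASS", or the position falls outside the capture intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

from intervaltree import IntervalTree

__all__ = [
    "Genotype",
    "GenotypeCall",
    "SiteQC",
    "VariantSite",
    "CaptureRegions",
    "FilterVerdict",
    "filter_genotype",
    "filter_site",
    "apply_qc",
    "QCResult",
]


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at a site with its QC fields.

    ``allele_balance`` is alt-supporting reads over total reads; it is
    meaningful (and filtered) only for heterozygous calls.
    """

    sample_id: str
    genotype: Genotype
    depth: Optional[int] = None
    allele_balance: Optional[float] = None
    genotype_quality: Optional[float] = None

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.allele_balance is not None and not 0 <= self.allele_balance <= 1:
            raise ValueError("allele_balance must lie in [0, 1]")

    @property
    def carries_alt(self) -> bool:
        return self.genotype in (Genotype.HET, Genotype.HOM_ALT)


@dataclass(frozen=True)
class SiteQC:
    missingness: float
    mappability: float
    vqsr_tranche: float
    filter_status: str = "PASS"

    def __post_init__(self) -> None:
        if not 0 <= self.missingness <= 1:
            raise ValueError("missingness must lie in [0, 1]")
        if not 0 <= self.mappability <= 1:
            raise ValueError("mappability must lie in [0, 1]")


@dataclass(frozen=True)
class VariantSite:
    """A bi-allelic variant site with its QC summary and genotype calls.

    Multi-allelic records must be decomposed to one alt per site before
    filtering so that per-alt QC fields are unambiguous.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    site_qc: SiteQC
    calls: tuple[GenotypeCall, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        object.__setattr__(self, "calls", tuple(self.calls))


class CaptureRegions:
    """Capture intervals, half-open 0-based per chromosome (BED convention).

    A variant is in-region when its 1-based start position lies inside the
    union of intervals; the union is what matters, not how it is split.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        self._trees: dict[str, IntervalTree] = {}
        n = 0
        for chrom, start, end in intervals:
            if start < 0 or end <= start:
                raise ValueError(f"malformed interval {(chrom, start, end)}")
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
            n += 1
        if n == 0:
            raise ValueError("capture regions are empty")
        for tree in self._trees.values():
            tree.merge_overlaps(strict=False)

    @classmethod
    def from_bed(cls, path) -> "CaptureRegions":
        intervals = []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{i}: BED line has fewer than 3 fields")
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(intervals)

    def contains(self, chrom: str, pos_1based: int) -> bool:
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return bool(tree.overlap(pos_1based - 1, pos_1based))

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    reason: Optional[str] = None  # first failing criterion, None on pass

    def __bool__(self) -> bool:
        return self.passed


def filter_genotype(call: GenotypeCall) -> FilterVerdict:
    """Per-genotype hard filter: depth <= 8, AB <= 0.20, GQ < 30 exclude.

    Missing genotypes pass vacuously (they carry no alt allele to count).
    The allele-balance cutoff targets suspect het calls; hom-alt calls are
    exempt from it.  Absent QC fields on a non-missing genotype are an
    error naming the field.
    """
    if call.genotype is Genotype.MISSING:
        return FilterVerdict(True)
    if call.depth is None:
        raise ValueError(f"sample {call.sample_id}: depth missing on non-missing genotype")
    if call.genotype_quality is None:
        raise ValueError(
            f"sample {call.sample_id}: genotype_quality missing on non-missing genotype"
        )
    if call.genotype is Genotype.HET and call.allele_balance is None:
        raise ValueError(
            f"sample {call.sample_id}: allele_balance missing on het genotype"
        )
    if call.depth <= 8:
        return FilterVerdict(False, "depth")
    if call.genotype is Genotype.HET and call.allele_balance <= 0.20:
        return FilterVerdict(False, "allele_balance")
    if call.genotype_quality < 30:
        return FilterVerdict(False, "genotype_quality")
    return FilterVerdict(True)


def filter_site(site: VariantSite, regions: CaptureRegions) -> FilterVerdict:
    """Per-site hard filter; reason names the first failing criterion."""
    qc = site.site_qc
    if qc.missingness > 0.10:
        return FilterVerdict(False, "missingness")
    if qc.mappability < 1:
        return FilterVerdict(False, "mappability")
    if qc.vqsr_tranche < 99.6:
        return FilterVerdict(False, "vqsr")
    if qc.filter_status != "PASS":
        return FilterVerdict(False, "filter_status")
    if not regions.contains(site.chrom, site.pos):
        return FilterVerdict(False, "outside_capture")
    return FilterVerdict(True)


@dataclass
class QCResult:
    sites: list[VariantSite]
    site_exclusions: dict[str, int] = field(default_factory=dict)
    genotype_exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def n_excluded_sites(self) -> int:
        return sum(self.site_exclusions.values())


def apply_qc(sites: Iterable[VariantSite], regions: CaptureRegions) -> QCResult:
    """Filter sites and their genotype calls, tallying exclusions.

    A site that passes all site-level filters is retained even when every
    one of its genotype calls fails (it then contributes zero carriers);
    failing genotype calls are replaced by missing calls so downstream
    counting sees no alt allele.
    """
    kept: list[VariantSite] = []
    site_tally: dict[str, int] = {}
    gt_tally: dict[str, int] = {}
    for site in sites:
        verdict = filter_site(site, regions)
        if not verdict:
            site_tally[verdict.reason] = site_tally.get(verdict.reason, 0) + 1
            continue
        new_calls = []
        for call in site.calls:
            gv = filter_genotype(call)
            if gv:
                new_calls.append(call)
            else:
                gt_tally[gv.reason] = gt_tally.get(gv.reason, 0) + 1
                new_calls.append(
                    GenotypeCall(sample_id=call.sample_id, genotype=Genotype.MISSING)
                )
        kept.append(replace(site, calls=tuple(new_calls)))
    return QCResult(kept, site_tally, gt_tally)
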