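"""De novo mutation burden: expected counts and exact Poisson tests.

The background model: each coding position mutates per generation at a
rate given by a tri-nucleotide context table (5' base, ref, 3' base ->
alt), so the number of de novo variants of a given consequence class
expected in a trio cohort is

    m0 = 2 * n_trios * sum over mappable positions and alts in class of rate,

the factor 2 counting the two transmitted haploid genomes per trio.
Observed counts m1 are compared to m0 with an exact one-sided Poisson
test; enrichment is m1 / m0.

The rate table is an input file (published tables are not reprinted
here); a documented toy table ships with the tests.  Only substitutions
are rate-modelled; de novo indels are counted but carry no expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .qc import Genotype

__all__ = [
    "BASES",
    "TrinucRateTable",
    "MappableCodingSequence",
    "DeNovoEnrichmentResult",
    "annotate_cds",
    "expected_count",
    "expected_count_table",
    "poisson_enrichment",
    "classify_inheritance",
    "CODON_TABLE",
]

BASES = ("A", "C", "G", "T")

# Standard nuclear codon table.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class TrinucRateTable:
    """Per-generation substitution rates keyed by (5', ref, 3', alt)."""

    def __init__(self, rates: dict[tuple[str, str, str, str], float]):
        for key, r in rates.items():
            if r < 0:
                raise ValueError(f"negative rate for context {key}")
            five, ref, three, alt = key
            if ref == alt or any(b not in BASES for b in key):
                raise ValueError(f"malformed context key {key}")
        self._rates = dict(rates)

    @classmethod
    def uniform(cls, rate: float) -> "TrinucRateTable":
        """Every context/alt at the same rate (64 contexts x 3 alts)."""
        rates = {}
        for five in BASES:
            for ref in BASES:
                for three in BASES:
                    for alt in BASES:
                        if alt != ref:
                            rates[(five, ref, three, alt)] = rate
        return cls(rates)

    @classmethod
    def from_tsv(cls, path) -> "TrinucRateTable":
        """Read a TSV with columns ``context`` (trinucleotide), ``alt``, ``rate``."""
        df = pd.read_csv(path, sep="\t", dtype={"context": str, "alt": str})
        rates = {}
        for row in df.itertuples(index=False):
            ctx = row.context.upper()
            if len(ctx) != 3:
                raise ValueError(f"context {ctx!r} is not a trinucleotide")
            rates[(ctx[0], ctx[1], ctx[2], row.alt.upper())] = float(row.rate)
        return cls(rates)

    def rate(self, five: str, ref: str, three: str, alt: str) -> float:
        return self._rates.get((five, ref, three, alt), 0.0)

    def total(self) -> float:
        return float(sum(self._rates.values()))

    def items(self):
        return self._rates.items()

    def to_tsv(self, path) -> None:
        rows = [
            {"context": f"{k[0]}{k[1]}{k[2]}", "alt": k[3], "rate": v}
            for k, v in sorted(self._rates.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class MappableCodingSequence:
    """Uniquely mappable coding sequence with per-substitution consequences.

    ``sequence`` is the in-frame CDS (with one flanking base on each side
    available via ``flank5``/``flank3`` for edge contexts); ``annotation``
    maps (0-based CDS position, alt base) -> consequence-class string in
    {"synonymous", "missense", "LGD", "other"}.  ``mappable`` marks which
    CDS positions are uniquely mappable (default: all).
    """

    gene: str
    sequence: str
    annotation: dict[tuple[int, str], str]
    flank5: str = "N"
    flank3: str = "N"
    mappable: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set(BASES):
            raise ValueError("sequence must be over {A,C,G,T}")
        if self.mappable is None:
            self.mappable = np.ones(len(self.sequence), dtype=bool)
        elif len(self.mappable) != len(self.sequence):
            raise ValueError("mappability mask length mismatch")

    def context(self, pos: int) -> Optional[tuple[str, str, str]]:
        """Trinucleotide context at 0-based ``pos``; None at an edge without flank."""
        seq = self.sequence
        five = seq[pos - 1] if pos > 0 else self.flank5
        three = seq[pos + 1] if pos < len(seq) - 1 else self.flank3
        if five not in BASES or three not in BASES:
            return None
        return five, seq[pos], three


def annotate_cds(gene: str, sequence: str, flank5: str = "N", flank3: str = "N") -> MappableCodingSequence:
    """Build per-substitution consequence annotation for an in-frame CDS.

    Each possible single-base substitution is translated through the codon
    table: a change creating a stop codon is LGD (premature stopgain,
    except in the final codon where stop loss/retention is "other"), a
    silent change synonymous, an amino-acid change missense, and loss of
    an existing stop "other".
    """
    sequence = sequence.upper()
    if len(sequence) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    annotation: dict[tuple[int, str], str] = {}
    n_codons = len(sequence) // 3
    for ci in range(n_codons):
        codon = sequence[3 * ci : 3 * ci + 3]
        aa = CODON_TABLE[codon]
        for offset in range(3):
            pos = 3 * ci + offset
            for alt in BASES:
                if alt == sequence[pos]:
                    continue
                mutant = codon[:offset] + alt + codon[offset + 1 :]
                new_aa = CODON_TABLE[mutant]
                if new_aa == aa:
                    cls = "synonymous"
                elif new_aa == "*":
                    # stopgain in the last codon is not premature
                    cls = "LGD" if ci < n_codons - 1 else "other"
                elif aa == "*":
                    cls = "other"  # stop loss
                else:
                    cls = "missense"
                annotation[(pos, alt)] = cls
    return MappableCodingSequence(gene, sequence, annotation, flank5, flank3)


def expected_count(
    rates: TrinucRateTable,
    seqs: MappableCodingSequence | Iterable[MappableCodingSequence],
    n_trios: int,
    variant_class: str = "all",
) -> float:
    """Expected de novo count m0 for a consequence class in a trio cohort.

    Positions whose trinucleotide context is undefined (sequence edge with
    no flank) are skipped.  m0 is linear in ``n_trios`` and additive over
    sequences.
    """
    if n_trios <= 0:
        raise ValueError("n_trios must be positive")
    valid = {"synonymous", "missense", "LGD", "other", "all"}
    if variant_class not in valid:
        raise ValueError(f"variant_class must be one of {sorted(valid)}")
    if isinstance(seqs, MappableCodingSequence):
        seqs = [seqs]
    total = 0.0
    n_skipped = 0
    for seq in seqs:
        for pos in range(len(seq.sequence)):
            if not seq.mappable[pos]:
                continue
            ctx = seq.context(pos)
            if ctx is None:
                n_skipped += 1
                continue
            five, ref, three = ctx
            for alt in BASES:
                if alt == ref:
                    continue
                cls = seq.annotation.get((pos, alt))
                if cls is None:
                    continue
                if variant_class == "all" or cls == variant_class:
                    total += rates.rate(five, ref, three, alt)
    if n_skipped:
        import logging

        logging.getLogger(__name__).info(
            "expected_count: skipped %d position(s) with undefined context", n_skipped
        )
    return 2.0 * n_trios * total


def expected_count_table(
    rates: TrinucRateTable,
    seqs: Iterable[MappableCodingSequence],
    n_trios: int,
) -> pd.DataFrame:
    """m0 per consequence class plus the 'all' total, one pass per class."""
    seqs = list(seqs)
    rows = []
    for cls in ("synonymous", "missense", "LGD", "other", "all"):
        rows.append({"variant_class": cls, "m0": expected_count(rates, seqs, n_trios, cls)})
    return pd.DataFrame(rows)


@dataclass
class DeNovoEnrichmentResult:
    variant_class: str
    m1: int
    m0: float
    enrichment: float
    p_value: float


def poisson_enrichment(m1: int, m0: float, variant_class: str = "all") -> DeNovoEnrichmentResult:
    """Exact one-sided Poisson test of observed vs expected de novo count.

    p = P(X >= m1) for X ~ Poisson(m0); enrichment = m1 / m0.
    """
    if m0 <= 0:
        raise ValueError("m0 must be positive")
    if m1 < 0 or int(m1) != m1:
        raise ValueError("m1 must be a non-negative integer")
    p = float(stats.poisson.sf(m1 - 1, m0))  # upper tail incl. m1
    return DeNovoEnrichmentResult(variant_class, int(m1), float(m0), m1 / m0, p)


@dataclass(frozen=True)
class InheritanceCall:
    status: str  # "de_novo", "inherited", "unknown"
    detail: Optional[str] = None
    mendelian_violation: bool = False


def classify_inheritance(
    child: Genotype, mother: Genotype, father: Genotype
) -> InheritanceCall:
    """Trio inheritance of an alt allele carried by the child.

    de novo: child carries the alt and both parents are hom-ref.
    inherited: a parent carries it (detail says which; "biparental" when
    both do).  unknown: a parent's genotype is missing — detail keeps the
    usual "<parent> or de novo" phrasing when the other parent is hom-ref.
    A child homozygous for the alt with only one carrier parent is flagged
    as a Mendelian violation (one allele is unexplained).
    """
    if child in (Genotype.MISSING, Genotype.HOM_REF):
        return InheritanceCall("unknown", "child carries no alt allele")
    m_carries = mother in (Genotype.HET, Genotype.HOM_ALT)
    f_carries = father in (Genotype.HET, Genotype.HOM_ALT)
    if mother is Genotype.MISSING or father is Genotype.MISSING:
        known, carries = (
            ("maternal", m_carries) if father is Genotype.MISSING else ("paternal", f_carries)
        )
        other = "paternal" if known == "maternal" else "maternal"
        if carries:
            return InheritanceCall("inherited", known)
        return InheritanceCall("unknown", f"{other} or de novo")
    if not m_carries and not f_carries:
        return InheritanceCall(
            "de_novo",
            None,
            mendelian_violation=(child is Genotype.HOM_ALT),
        )
    if m_carries and f_carries:
        return InheritanceCall("inherited", "biparental")
    detail = "maternal" if m_carries else "paternal"
    violation = child is Genotype.HOM_ALT and not (m_carries and f_carries)
    return InheritanceCall("inherited", detail, mendelian_violation=violation)
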