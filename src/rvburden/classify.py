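"""Rarity and deleteriousness classification of annotated variants.

Qualifying variants for the burden test are rare (population allele
frequency < 0.01% in both ExAC and gnomAD WES; absent treated as 0) and
deleterious, where deleterious means either likely gene-disrupting (LGD:
premature stopgain, frameshift indel, canonical splice-site variant, or
exon deletion) or damaging missense (D-mis: missense with REVEL > 0.5).
Synonymous variants are tracked separately as the batch-effect calibration
class; everything else (including in-frame indels) is "other".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import pandas as pd

__all__ = [
    "Consequence",
    "DeleteriousnessClass",
    "AnnotatedVariant",
    "is_rare",
    "classify",
    "consequence_from_alleles",
    "classify_table",
    "RARE_AF_CUTOFF",
    "REVEL_CUTOFF",
]

logger = logging.getLogger(__name__)

RARE_AF_CUTOFF = 1e-4  # AF < 0.01%
REVEL_CUTOFF = 0.5  # D-mis: REVEL strictly > 0.5
CANONICAL_SPLICE_BP = 2  # intronic bases at each exon boundary


class Consequence(str, Enum):
    STOPGAIN = "stopgain"
    FRAMESHIFT_INDEL = "frameshift_indel"
    CANONICAL_SPLICE = "canonical_splice"
    EXON_DELETION = "exon_deletion"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


LGD_CONSEQUENCES = frozenset(
    {
        Consequence.STOPGAIN,
        Consequence.FRAMESHIFT_INDEL,
        Consequence.CANONICAL_SPLICE,
        Consequence.EXON_DELETION,
    }
)


class DeleteriousnessClass(str, Enum):
    LGD = "LGD"
    D_MIS = "D_mis"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


@dataclass(frozen=True)
class AnnotatedVariant:
    """One variant with gene, consequence, population AFs and scores.

    REVEL is required for missense variants entering D-mis decisions; CADD
    is carried as metadata only and never used for classification.
    """

    gene: str
    consequence: Consequence
    af_exac: Optional[float] = None
    af_gnomad_wes: Optional[float] = None
    revel: Optional[float] = None
    cadd: Optional[float] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("af_exac", "af_gnomad_wes"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.revel is not None and not 0 <= self.revel <= 1:
            raise ValueError(f"revel must lie in [0, 1], got {self.revel}")


def is_rare(
    variant: AnnotatedVariant, af_cutoff: float = RARE_AF_CUTOFF
) -> bool:
    """True when every available population AF is below the cutoff.

    An absent AF means the allele was not seen in that reference and is
    treated as frequency 0 (rare).
    """
    for af in (variant.af_exac, variant.af_gnomad_wes):
        if af is not None and af >= af_cutoff:
            return False
    return True


def classify(
    variant: AnnotatedVariant, revel_cutoff: float = REVEL_CUTOFF
) -> DeleteriousnessClass:
    """Assign exactly one deleteriousness class from the annotation.

    Missense with REVEL strictly above the cutoff is D-mis; missense with
    an absent REVEL score cannot be called damaging and falls to "other"
    with a logged warning.
    """
    cons = variant.consequence
    if cons in LGD_CONSEQUENCES:
        return DeleteriousnessClass.LGD
    if cons is Consequence.MISSENSE:
        if variant.revel is None:
            logger.warning(
                "missense variant %s %s:%s with absent REVEL classed 'other'",
                variant.gene, variant.chrom, variant.pos,
            )
            return DeleteriousnessClass.OTHER
        if variant.revel > revel_cutoff:
            return DeleteriousnessClass.D_MIS
        return DeleteriousnessClass.OTHER
    if cons is Consequence.SYNONYMOUS:
        return DeleteriousnessClass.SYNONYMOUS
    return DeleteriousnessClass.OTHER


# ANNOVAR-style exonic/splicing function labels -> consequence enum.
_LABEL_MAP = {
    "stopgain": Consequence.STOPGAIN,
    "stopgain snv": Consequence.STOPGAIN,
    "frameshift insertion": Consequence.FRAMESHIFT_INDEL,
    "frameshift deletion": Consequence.FRAMESHIFT_INDEL,
    "frameshift substitution": Consequence.FRAMESHIFT_INDEL,
    "frameshift_indel": Consequence.FRAMESHIFT_INDEL,
    "splicing": Consequence.CANONICAL_SPLICE,
    "canonical_splice": Consequence.CANONICAL_SPLICE,
    "exon_deletion": Consequence.EXON_DELETION,
    "nonsynonymous snv": Consequence.MISSENSE,
    "missense": Consequence.MISSENSE,
    "synonymous snv": Consequence.SYNONYMOUS,
    "synonymous": Consequence.SYNONYMOUS,
    "nonframeshift insertion": Consequence.OTHER,
    "nonframeshift deletion": Consequence.OTHER,
    "stoploss": Consequence.OTHER,
    "other": Consequence.OTHER,
}


def consequence_from_alleles(
    ref: str,
    alt: str,
    annotation_context: Optional[str] = None,
    in_cds: bool = True,
    distance_to_exon_boundary: Optional[int] = None,
) -> Consequence:
    """Map an annotation label and/or allele pair to a consequence.

    Precedence: an intronic position within 2 bp of an exon boundary is a
    canonical splice variant; a CDS indel whose length change is not a
    multiple of 3 is a frameshift; otherwise the recognised label decides.
    Unknown labels map to "other" with a logged warning.
    """
    if distance_to_exon_boundary is not None and 1 <= distance_to_exon_boundary <= CANONICAL_SPLICE_BP:
        return Consequence.CANONICAL_SPLICE
    if in_cds and len(ref) != len(alt):
        if (len(ref) - len(alt)) % 3 != 0:
            return Consequence.FRAMESHIFT_INDEL
        # in-frame indel: deliberately not LGD
        return Consequence.OTHER
    if annotation_context is not None:
        key = annotation_context.strip().lower()
        if key in _LABEL_MAP:
            return _LABEL_MAP[key]
        logger.warning("unknown consequence label %r mapped to 'other'", annotation_context)
        return Consequence.OTHER
    return Consequence.OTHER


def classify_table(
    variants: pd.DataFrame,
    af_cutoff: float = RARE_AF_CUTOFF,
    revel_cutoff: float = REVEL_CUTOFF,
) -> pd.DataFrame:
    """Vectorised rarity + class annotation of a variant table.

    Expects columns ``gene``, ``consequence`` and optionally ``af_exac``,
    ``af_gnomad_wes``, ``revel``; adds ``rare`` (bool) and ``dclass``.
    """
    df = variants.copy()
    for col in ("af_exac", "af_gnomad_wes", "revel"):
        if col not in df.columns:
            df[col] = pd.NA
    af_e = pd.to_numeric(df["af_exac"], errors="coerce")
    af_g = pd.to_numeric(df["af_gnomad_wes"], errors="coerce")
    if (af_e.fillna(0) < 0).any() or (af_g.fillna(0) < 0).any():
        raise ValueError("negative allele frequency")
    df["rare"] = (af_e.fillna(0.0) < af_cutoff) & (af_g.fillna(0.0) < af_cutoff)

    cons = df["consequence"].map(lambda c: Consequence(c) if not isinstance(c, Consequence) else c)
    revel = pd.to_numeric(df["revel"], errors="coerce")
    dclass = pd.Series(DeleteriousnessClass.OTHER.value, index=df.index, dtype=object)
    dclass[cons.isin(LGD_CONSEQUENCES)] = DeleteriousnessClass.LGD.value
    dclass[(cons == Consequence.MISSENSE) & (revel > revel_cutoff)] = DeleteriousnessClass.D_MIS.value
    dclass[cons == Consequence.SYNONYMOUS] = DeleteriousnessClass.SYNONYMOUS.value
    n_no_revel = int(((cons == Consequence.MISSENSE) & revel.isna()).sum())
    if n_no_revel:
        logger.warning("%d missense variant(s) with absent REVEL classed 'other'", n_no_revel)
    df["dclass"] = dclass
    return df
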