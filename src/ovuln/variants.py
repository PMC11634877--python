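"""Somatic variant consensus filtering, TMB and neoantigen load.

Variants are assumed to come from a tumor/normal pair called by four
callers (Mutect2, SomaticSniper, Varscan2, Strelka2).  A variant passes the
consensus filter when at least two callers support it, its tumor variant
allele frequency is >= 0.05 and its normal VAF is < 0.05.  Tumor mutational
burden counts nonsynonymous SNVs per megabase; neoantigen load counts
predicted MHC-I binders per megabase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

CALLERS = ("mutect2", "somaticsniper", "varscan2", "strelka2")

CONSEQUENCES = ("nonsynonymous_snv", "synonymous_snv", "indel", "other")

#: default exome footprint used as the per-megabase denominator
DEFAULT_EXOME_MB = 30.0

# consensus filter thresholds
MIN_CALLERS = 2
MIN_TUMOR_VAF = 0.05
MAX_NORMAL_VAF = 0.05  # exclusive

# binder %rank thresholds (strict <)
WEAK_RANK = 2.0
STRONG_RANK = 0.5


@dataclass
class VariantRecord:
    """One somatic variant with per-caller support and tumor/normal VAF."""

    chrom: str
    pos: int
    ref: str
    alt: str
    mutect2: bool
    somaticsniper: bool
    varscan2: bool
    strelka2: bool
    tumor_vaf: float
    normal_vaf: float
    consequence: str = "other"
    pathogenicity_class: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        for name in ("tumor_vaf", "normal_vaf"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
            setattr(self, name, v)
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"unknown consequence {self.consequence!r}; expected one of {CONSEQUENCES}"
            )
        if self.pathogenicity_class is not None and self.pathogenicity_class not in (1, 2, 3, 4, 5):
            raise ValueError(
                f"pathogenicity_class must be 1-5 or None, got {self.pathogenicity_class}"
            )
        for c in CALLERS:
            setattr(self, c, bool(getattr(self, c)))

    @property
    def caller_count(self) -> int:
        return sum(getattr(self, c) for c in CALLERS)

    @property
    def supporting_callers(self) -> list[str]:
        return [c for c in CALLERS if getattr(self, c)]


@dataclass
class BinderPrediction:
    """A peptide-MHC binding prediction (percentile rank; lower = stronger)."""

    peptide: str
    hla_allele: str
    percent_rank: float

    def __post_init__(self) -> None:
        if not 8 <= len(self.peptide) <= 11:
            raise ValueError(
                f"peptide length must be 8-11 amino acids, got {len(self.peptide)}"
            )
        self.percent_rank = float(self.percent_rank)
        if self.percent_rank <= 0:
            raise ValueError(f"percent_rank must be positive, got {self.percent_rank}")


@dataclass
class NeoantigenLoad:
    weak_count: int
    strong_count: int
    load: float


def consensus_filter(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Keep variants with >=2 caller support, tumor VAF >= 0.05, normal VAF < 0.05.

    "Two of four" is read as at-least-two: a variant seen by three or four
    callers also passes.  Boundaries are inclusive on the tumor side and
    exclusive on the normal side.
    """
    return [
        v
        for v in variants
        if v.caller_count >= MIN_CALLERS
        and v.tumor_vaf >= MIN_TUMOR_VAF
        and v.normal_vaf < MAX_NORMAL_VAF
    ]


def pathogenic_only(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Keep pathogenic (class 5) and likely pathogenic (class 4) variants only.

    Records without a pathogenicity annotation are dropped.
    """
    return [v for v in variants if v.pathogenicity_class in (4, 5)]


def tmb(variants: Sequence[VariantRecord], exome_size_mb: float = DEFAULT_EXOME_MB) -> float:
    """Tumor mutational burden: nonsynonymous SNVs per megabase.

    Indels and synonymous variants do not count.  ``variants`` should
    already be consensus-filtered.
    """
    if exome_size_mb <= 0:
        raise ValueError(f"exome_size_mb must be positive, got {exome_size_mb}")
    n = sum(v.consequence == "nonsynonymous_snv" for v in variants)
    return n / exome_size_mb


def neoantigen_load(
    binders: Iterable[BinderPrediction], exome_size_mb: float = DEFAULT_EXOME_MB
) -> NeoantigenLoad:
    """Count weak (%rank < 2) and strong (%rank < 0.5) binders per megabase.

    Under the strict-< thresholds every strong binder is also a weak
    binder, so the union of weak and strong binders is the weak set; the
    reported load is therefore weak_count / exome_size_mb, with
    strong_count reported separately.  Peptide length (8-11) and HLA allele
    never restrict counting.
    """
    if exome_size_mb <= 0:
        raise ValueError(f"exome_size_mb must be positive, got {exome_size_mb}")
    weak = strong = 0
    for b in binders:
        if b.percent_rank < WEAK_RANK:
            weak += 1
        if b.percent_rank < STRONG_RANK:
            strong += 1
    return NeoantigenLoad(weak_count=weak, strong_count=strong, load=weak / exome_size_mb)
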