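"""Rule-based BRCAness ground-truth labeling from genomic features.

A sample is labeled BRCAness when any one of four criteria holds:

* a deleterious (pathogenic/likely pathogenic) mutation in a homologous
  recombination repair (HRR) pathway gene,
* an ovarian cancer-specific HRD score (LOH + TAI + LST) >= 63,
* a mutational signature 3 ratio > 0.25,
* BRCA1 promoter methylation beta value > 0.7.

Missing assays (no methylation value, zero total mutations) conservatively
count as criterion-not-met; the rule is a disjunction, so missingness can
only withhold a BRCAness call, never create one.

The methylation criterion is applied to a single per-sample beta value.
The source cohort reports BRCA1 promoter methylation; whether BRCA2
promoters were also assayed is ambiguous in the literature, so the field is
documented as BRCA1 but accepts whatever promoter beta the caller supplies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .matrix import GenomicProfile

__all__ = [
    "HRD_SCORE_CUTOFF",
    "SIG3_RATIO_CUTOFF",
    "METHYLATION_BETA_CUTOFF",
    "DEFAULT_HRR_GENES",
    "BRCAnessLabel",
    "hrd_score",
    "sig3_ratio",
    "assign_brcaness_label",
    "label_cohort",
]

#: ovarian cancer-specific HRD score cutoff (inclusive: >= 63 triggers)
HRD_SCORE_CUTOFF = 63
#: mutational signature 3 ratio cutoff (strict: > 0.25 triggers)
SIG3_RATIO_CUTOFF = 0.25
#: BRCA1 promoter methylation beta cutoff (strict: > 0.7 triggers)
METHYLATION_BETA_CUTOFF = 0.7

CRITERIA = ("HRR_MUTATION", "HRD_SCORE", "SIG3_RATIO", "BRCA1_METHYLATION")

#: Default homologous recombination repair pathway gene list used when
#: flagging deleterious mutations upstream of the profile table.  The rule
#: itself consumes a per-sample boolean; this list documents which genes a
#: caller would typically count and is fully configurable.
DEFAULT_HRR_GENES = (
    "BRCA1", "BRCA2", "PALB2", "RAD51", "RAD51B", "RAD51C", "RAD51D",
    "ATM", "ATR", "BARD1", "BRIP1", "CHEK1", "CHEK2", "CDK12",
    "FANCA", "FANCD2", "FANCL", "MRE11", "NBN", "RAD54L",
)


@dataclass
class BRCAnessLabel:
    sample_id: str
    label: str  # "BRCAness" | "noBRCAness"
    triggered_criteria: list[str] = field(default_factory=list)
    hrd_score: int = 0
    sig3_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.label not in ("BRCAness", "noBRCAness"):
            raise ValueError(f"unknown label {self.label!r}")
        unknown = set(self.triggered_criteria) - set(CRITERIA)
        if unknown:
            raise ValueError(f"unknown criteria: {sorted(unknown)}")
        if (self.label == "BRCAness") != bool(self.triggered_criteria):
            raise ValueError(
                "label must be BRCAness if and only if at least one criterion triggered"
            )

    @property
    def is_brcaness(self) -> bool:
        return self.label == "BRCAness"


def hrd_score(loh: int, tai: int, lst: int) -> int:
    """Unweighted sum of the three genomic scar counts."""
    for name, v in (("loh", loh), ("tai", tai), ("lst", lst)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    return int(loh) + int(tai) + int(lst)


def sig3_ratio(sig3_mutations: int, total_mutations: int) -> float | None:
    """Signature-3-attributed mutations over all mutations; None if no mutations."""
    if sig3_mutations < 0:
        raise ValueError(f"sig3_mutations must be non-negative, got {sig3_mutations}")
    if total_mutations < 0:
        raise ValueError(f"total_mutations must be non-negative, got {total_mutations}")
    if sig3_mutations > total_mutations:
        raise ValueError(
            f"sig3_mutations ({sig3_mutations}) exceeds total_mutations ({total_mutations})"
        )
    if total_mutations == 0:
        return None
    return sig3_mutations / total_mutations


def assign_brcaness_label(
    profile: GenomicProfile,
    *,
    hrd_cutoff: int = HRD_SCORE_CUTOFF,
    sig3_cutoff: float = SIG3_RATIO_CUTOFF,
    methylation_cutoff: float = METHYLATION_BETA_CUTOFF,
) -> BRCAnessLabel:
    """Apply the four-criterion disjunction to one genomic profile.

    Boundary semantics follow the published rule exactly: the HRD cutoff is
    inclusive (>= 63), the signature 3 and methylation cutoffs are strict
    (> 0.25, > 0.7).
    """
    score = hrd_score(profile.loh, profile.tai, profile.lst)
    ratio = sig3_ratio(profile.sig3_mutations, profile.total_mutations)

    triggered: list[str] = []
    if profile.hrr_pathogenic_mutation:
        triggered.append("HRR_MUTATION")
    if score >= hrd_cutoff:
        triggered.append("HRD_SCORE")
    if ratio is not None and ratio > sig3_cutoff:
        triggered.append("SIG3_RATIO")
    beta = profile.brca1_promoter_beta
    if beta is not None and beta > methylation_cutoff:
        triggered.append("BRCA1_METHYLATION")

    return BRCAnessLabel(
        sample_id=profile.sample_id,
        label="BRCAness" if triggered else "noBRCAness",
        triggered_criteria=triggered,
        hrd_score=score,
        sig3_ratio=ratio,
    )


def label_cohort(profiles: Iterable[GenomicProfile], **kwargs) -> list[BRCAnessLabel]:
    return [assign_brcaness_label(p, **kwargs) for p in profiles]
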