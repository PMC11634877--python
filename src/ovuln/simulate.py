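"""Synthetic cohorts with the statistical structure the pipeline assumes.

The bulk generator emulates a two-class (BRCAness / noBRCAness) tumor
cohort: expression is Gaussian on the log2(TPM+1) scale floored at zero,
with a subset of informative genes shifted upward in BRCAness samples, and
per-sample genomic profiles constructed so that the rule-based truth
labeling reproduces the drawn classes exactly.  The single-cell generator
gives each sample a latent class-dependent profile and draws cells around
it; the variant and response generators exercise the consensus filter and
the logistic weight fit with documented marginals.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import PUBLISHED_SIGNATURE_GENES
from .matrix import ExpressionMatrix, GenomicProfile
from .truth import BRCAnessLabel, assign_brcaness_label
from .variants import CALLERS, CONSEQUENCES, VariantRecord
from .vulnerability import VulnerabilityWeights

__all__ = [
    "MARKER_GENES",
    "CohortSpec",
    "SyntheticCohort",
    "SyntheticSingleCell",
    "generate_cohort",
    "generate_single_cell",
    "generate_variants",
    "generate_response_cohort",
    "VARIANT_PASS_PROBABILITY",
]

#: marker genes always present in generated panels so that CYT, the
#: CYT-to-C1QA ratio and the published partial signature can be evaluated
MARKER_GENES = ("GZMB", "PRF1", "C1QA") + PUBLISHED_SIGNATURE_GENES


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic bulk cohort.

    ``effect_size`` is the log2-scale mean shift of informative genes in
    the BRCAness class; ``noise_sd`` the per-gene Gaussian noise standard
    deviation; ``class_fraction`` the expected BRCAness fraction.
    """

    n_samples: int = 200
    n_genes: int = 500
    n_informative: int = 20
    effect_size: float = 2.0
    class_fraction: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_informative > self.n_genes - len(MARKER_GENES):
            raise ValueError(
                f"n_informative ({self.n_informative}) exceeds available non-marker "
                f"genes ({self.n_genes - len(MARKER_GENES)})"
            )
        if not 0.0 < self.class_fraction < 1.0:
            raise ValueError("class_fraction must be in (0, 1)")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if self.n_genes < len(MARKER_GENES) + 1:
            raise ValueError("n_genes too small to hold the marker panel")


@dataclass
class SyntheticCohort:
    expr: ExpressionMatrix
    profiles: list[GenomicProfile]
    labels: list[BRCAnessLabel]
    informative_genes: list[str] = field(default_factory=list)

    @property
    def classes(self) -> pd.Series:
        return pd.Series(
            {l.sample_id: l.label for l in self.labels}, name="label"
        ).loc[self.expr.sample_ids]


@dataclass
class SyntheticSingleCell:
    cell_expr: ExpressionMatrix
    sample_of_cell: dict[str, str]
    labels: list[BRCAnessLabel]


def _gene_panel(spec: CohortSpec) -> tuple[list[str], list[str]]:
    n_background = spec.n_genes - spec.n_informative - len(MARKER_GENES)
    informative = [f"DEG{i+1:04d}" for i in range(spec.n_informative)]
    background = [f"BG{i+1:04d}" for i in range(n_background)]
    return informative, informative + background + list(MARKER_GENES)


def _draw_classes(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    is_pos = rng.random(spec.n_samples) < spec.class_fraction
    # guarantee both classes so downstream training is always possible
    if is_pos.all():
        is_pos[rng.integers(spec.n_samples)] = False
    if not is_pos.any():
        is_pos[rng.integers(spec.n_samples)] = True
    return is_pos


def _draw_expression(
    rng: np.random.Generator, spec: CohortSpec, is_pos: np.ndarray
) -> tuple[ExpressionMatrix, list[str]]:
    informative, genes = _gene_panel(spec)
    samples = [f"S{i+1:04d}" for i in range(spec.n_samples)]
    baseline = rng.uniform(1.0, 6.0, size=len(genes))
    values = baseline[:, None] + rng.normal(0.0, spec.noise_sd, (len(genes), spec.n_samples))
    shift = np.isin(genes, informative)[:, None] & is_pos[None, :]
    values = values + spec.effect_size * shift
    values = np.maximum(values, 0.0)  # log2(TPM+1) scale is non-negative
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "log2tpm1")
    return expr, informative


def _draw_profile(
    rng: np.random.Generator, sample_id: str, positive: bool
) -> GenomicProfile:
    total = int(rng.integers(50, 200))
    if positive:
        # at least one criterion fires: high genomic scars and/or sig3 ratio
        mechanism = rng.integers(3)
        if mechanism == 0:  # HRD score >= 63
            loh, tai, lst = (int(rng.integers(21, 40)) for _ in range(3))
            sig3 = int(rng.integers(0, int(total * 0.2) + 1))
        elif mechanism == 1:  # signature 3 ratio > 0.25
            loh, tai, lst = (int(rng.integers(0, 20)) for _ in range(3))
            sig3 = int(np.ceil(total * rng.uniform(0.3, 0.6)))
        else:  # both scars and signature
            loh, tai, lst = (int(rng.integers(21, 40)) for _ in range(3))
            sig3 = int(np.ceil(total * rng.uniform(0.3, 0.6)))
        hrr = bool(rng.random() < 0.2)
        beta = float(rng.uniform(0.75, 0.95)) if rng.random() < 0.1 else float(rng.uniform(0.0, 0.5))
    else:
        loh, tai, lst = (int(rng.integers(0, 20)) for _ in range(3))
        sig3 = int(rng.integers(0, int(total * 0.2) + 1))
        hrr = False
        beta = float(rng.uniform(0.0, 0.5))
    return GenomicProfile(
        sample_id=sample_id,
        loh=loh,
        tai=tai,
        lst=lst,
        sig3_mutations=sig3,
        total_mutations=total,
        hrr_pathogenic_mutation=hrr,
        brca1_promoter_beta=beta,
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Bulk expression + genomic profiles + consistent truth labels."""
    rng = np.random.default_rng(spec.seed)
    is_pos = _draw_classes(rng, spec)
    expr, informative = _draw_expression(rng, spec, is_pos)
    profiles = [
        _draw_profile(rng, s, bool(p)) for s, p in zip(expr.sample_ids, is_pos)
    ]
    labels = [assign_brcaness_label(p) for p in profiles]
    # by construction the rule reproduces the drawn classes
    for lab, pos in zip(labels, is_pos):
        assert lab.is_brcaness == bool(pos)
    return SyntheticCohort(expr, profiles, labels, informative)


def generate_single_cell(
    n_samples: int,
    cells_per_sample: int,
    spec: CohortSpec,
) -> SyntheticSingleCell:
    """Per-cell expression where cells share their sample's class signal.

    Each sample has a noise-free latent profile (baseline plus class
    shift); cells are drawn around it with the spec's noise_sd, so one cell
    per sample reproduces the bulk generator's distribution.
    """
    if cells_per_sample < 1:
        raise ValueError("cells_per_sample must be >= 1")
    spec = CohortSpec(
        n_samples=n_samples,
        n_genes=spec.n_genes,
        n_informative=spec.n_informative,
        effect_size=spec.effect_size,
        class_fraction=spec.class_fraction,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
    )
    rng = np.random.default_rng(spec.seed)
    is_pos = _draw_classes(rng, spec)
    informative, genes = _gene_panel(spec)
    samples = [f"S{i+1:04d}" for i in range(n_samples)]
    baseline = rng.uniform(1.0, 6.0, size=len(genes))
    shift_mask = np.isin(genes, informative)

    cell_cols: list[str] = []
    sample_of_cell: dict[str, str] = {}
    blocks = []
    for j, (s, pos) in enumerate(zip(samples, is_pos)):
        latent = baseline + (spec.effect_size * shift_mask if pos else 0.0)
        cells = latent[:, None] + rng.normal(
            0.0, spec.noise_sd, (len(genes), cells_per_sample)
        )
        blocks.append(np.maximum(cells, 0.0))
        for k in range(cells_per_sample):
            cid = f"{s}_C{k+1:03d}"
            cell_cols.append(cid)
            sample_of_cell[cid] = s
    values = np.concatenate(blocks, axis=1)
    cell_expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=cell_cols), "log2tpm1"
    )
    profiles = [_draw_profile(rng, s, bool(p)) for s, p in zip(samples, is_pos)]
    labels = [assign_brcaness_label(p) for p in profiles]
    return SyntheticSingleCell(cell_expr, sample_of_cell, labels)


#: Marginals of generate_variants: the four caller flags are independent
#: Bernoulli(1/2), tumor VAF ~ U(0, 0.5), normal VAF ~ U(0, 0.1),
#: consequence uniform over the four tags, pathogenicity class uniform over
#: 1..5.  The consensus-filter pass probability in closed form is
#: P(>=2 callers) * P(tumor >= 0.05) * P(normal < 0.05)
#: = (11/16) * (0.45/0.5) * (0.05/0.1).
VARIANT_PASS_PROBABILITY = (11 / 16) * 0.9 * 0.5


def generate_variants(n_variants: int, seed: int = 0) -> list[VariantRecord]:
    """Random variants with the documented marginals above."""
    if n_variants < 0:
        raise ValueError("n_variants must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    bases = np.array(list("ACGT"))
    for i in range(n_variants):
        flags = rng.random(4) < 0.5
        ref, alt = rng.choice(bases, size=2, replace=False)
        out.append(
            VariantRecord(
                chrom=f"chr{int(rng.integers(1, 23))}",
                pos=int(rng.integers(1, 10_000_000)),
                ref=str(ref),
                alt=str(alt),
                mutect2=bool(flags[0]),
                somaticsniper=bool(flags[1]),
                varscan2=bool(flags[2]),
                strelka2=bool(flags[3]),
                tumor_vaf=float(rng.uniform(0.0, 0.5)),
                normal_vaf=float(rng.uniform(0.0, 0.1)),
                consequence=str(rng.choice(CONSEQUENCES)),
                pathogenicity_class=int(rng.integers(1, 6)),
            )
        )
    return out


def generate_response_cohort(
    n: int,
    weights: VulnerabilityWeights = VulnerabilityWeights(),
    seed: int = 0,
    intercept: float = -2.0,
) -> pd.DataFrame:
    """Covariates uniform on [0,1]; Bernoulli response from a logistic model.

    logit P(response) = intercept + w_brca * proxy + w_c2c * c2c.  The
    default intercept of -2 keeps the response rate near 50% under the
    shipped weights.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    proxy = rng.uniform(0.0, 1.0, n)
    c2c = rng.uniform(0.0, 1.0, n)
    logit = intercept + weights.w_brca * proxy + weights.w_c2c * c2c
    p = 1.0 / (1.0 + np.exp(-logit))
    response = (rng.random(n) < p).astype(int)
    return pd.DataFrame({"brca_proxy": proxy, "c2c": c2c, "response": response})
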