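"""Expression matrices, gene sets and per-sample genomic profiles.

The central container is :class:`ExpressionMatrix`, a validated genes x
samples table carrying a layer tag that records which scale the values are
on (raw counts, TPM, or log2(TPM+1)).  All downstream scoring and
classification operates on the ``log2tpm1`` layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LAYERS",
    "ExpressionMatrix",
    "GeneSet",
    "GenomicProfile",
    "normalize_tpm_log",
    "tpm_from_counts",
    "log2_tpm1",
]

LAYERS = ("counts", "tpm", "log2tpm1")

#: column sums of a TPM layer must equal this (library-size normalisation)
TPM_TOTAL = 1e6


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with a declared layer.

    Parameters
    ----------
    data
        DataFrame indexed by gene symbol with sample identifiers as
        columns.  Values must be numeric and complete; missing values are
        rejected rather than imputed because ranks and means downstream
        are undefined on missing data.
    layer
        One of ``counts``, ``tpm``, ``log2tpm1``.
    """

    data: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame (genes x samples)")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(values).any():
            raise ValueError("missing expression values are not permitted")
        if self.layer == "log2tpm1" and (values < 0).any():
            raise ValueError("log2(TPM+1) values must be non-negative")
        if self.layer == "counts" and (values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.layer == "tpm":
            sums = values.sum(axis=0)
            if not np.allclose(sums, TPM_TOTAL, rtol=1e-6):
                bad = [s for s, t in zip(self.data.columns, sums) if not np.isclose(t, TPM_TOTAL, rtol=1e-6)]
                raise ValueError(f"TPM columns must sum to 1e6; offending samples: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def gene(self, symbol: str) -> pd.Series:
        """Per-sample expression of one gene; KeyError names the gene."""
        if symbol not in self.data.index:
            raise KeyError(f"gene {symbol!r} not present in expression matrix")
        return self.data.loc[symbol]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not present in expression matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(genes)].copy(), self.layer)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not present in expression matrix: {missing}")
        return ExpressionMatrix(self.data[list(samples)].copy(), self.layer)


@dataclass
class GeneSet:
    """A named collection of gene symbols (e.g. one GMT line)."""

    name: str
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        # preserve order but drop duplicates (set semantics for membership)
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g, None)
        self.genes = list(seen)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def present_in(self, expr: ExpressionMatrix) -> list[str]:
        idx = set(expr.data.index)
        return [g for g in self.genes if g in idx]


@dataclass
class GenomicProfile:
    """Per-sample genomic features feeding the BRCAness ground-truth rule.

    ``loh``, ``tai`` and ``lst`` are the three genomic scar counts (loss of
    heterozygosity, telomeric allelic imbalance, large-scale state
    transitions); their unweighted sum is the HRD score.  ``sig3_mutations``
    over ``total_mutations`` is the mutational signature 3 ratio.
    ``brca1_promoter_beta`` is the BRCA1 promoter methylation beta value, or
    None when the assay is missing.
    """

    sample_id: str
    loh: int
    tai: int
    lst: int
    sig3_mutations: int
    total_mutations: int
    hrr_pathogenic_mutation: bool
    brca1_promoter_beta: float | None = None

    def __post_init__(self) -> None:
        for name in ("loh", "tai", "lst", "sig3_mutations", "total_mutations"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            setattr(self, name, int(v))
        if self.sig3_mutations > self.total_mutations:
            raise ValueError(
                f"sample {self.sample_id}: sig3_mutations ({self.sig3_mutations}) "
                f"exceeds total_mutations ({self.total_mutations})"
            )
        if self.brca1_promoter_beta is not None:
            beta = float(self.brca1_promoter_beta)
            if np.isnan(beta):
                self.brca1_promoter_beta = None
            elif not 0.0 <= beta <= 1.0:
                raise ValueError(
                    f"sample {self.sample_id}: methylation beta {beta} outside [0, 1]"
                )
            else:
                self.brca1_promoter_beta = beta
        self.hrr_pathogenic_mutation = bool(self.hrr_pathogenic_mutation)


def tpm_from_counts(counts: ExpressionMatrix, gene_lengths: Mapping[str, float]) -> ExpressionMatrix:
    """Transcripts-per-million from raw counts and gene lengths in bases.

    TPM_g = (count_g / length_g) / sum_h(count_h / length_h) * 1e6 per sample.
    """
    if counts.layer != "counts":
        raise ValueError(f"expected a counts layer, got {counts.layer!r}")
    missing = [g for g in counts.gene_ids if g not in gene_lengths]
    if missing:
        raise ValueError(f"missing gene lengths for: {missing[:10]}")
    lengths = np.array([float(gene_lengths[g]) for g in counts.gene_ids])
    if (lengths <= 0).any():
        bad = [g for g, l in zip(counts.gene_ids, lengths) if l <= 0]
        raise ValueError(f"gene lengths must be positive; offending genes: {bad[:10]}")
    rate = counts.values / lengths[:, None]
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = [s for s, z in zip(counts.sample_ids, zero) if z]
        raise ValueError(f"samples with all-zero counts cannot be normalized: {bad}")
    tpm = rate / totals[None, :] * TPM_TOTAL
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=counts.data.index, columns=counts.data.columns), "tpm"
    )


def log2_tpm1(tpm: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transform of a TPM layer."""
    if tpm.layer != "tpm":
        raise ValueError(f"expected a tpm layer, got {tpm.layer!r}")
    return ExpressionMatrix(np.log2(tpm.data + 1.0), "log2tpm1")


def normalize_tpm_log(
    counts: ExpressionMatrix, gene_lengths: Mapping[str, float]
) -> ExpressionMatrix:
    """Raw counts -> TPM -> log2(TPM+1), the layer every downstream step uses."""
    return log2_tpm1(tpm_from_counts(counts, gene_lengths))
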