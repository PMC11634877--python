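"""Immune signature scoring, cytolytic activity, and phenotype classification.

Signatures are scored per sample with a size-dependent rule: small sets
(<= 10 genes present in the matrix) use the mean log2(TPM+1) of their
members; larger sets use a rank-based single-sample enrichment z-score.
Cytolytic activity (CYT) is the mean log2(TPM+1) of GZMB and PRF1.
The tumor-immune phenotype (infiltrated / excluded / desert) is predicted
with a random forest over a caller-supplied gene list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .matrix import ExpressionMatrix, GeneSet

__all__ = [
    "MEAN_EXPRESSION_MAX_SIZE",
    "CYT_GENES",
    "PHENOTYPES",
    "SignatureScoreTable",
    "score_signatures",
    "rank_enrichment_z",
    "cytolytic_activity",
    "PhenotypeClassifier",
    "train_phenotype_classifier",
]

#: sets with at most this many genes present are scored by mean expression
MEAN_EXPRESSION_MAX_SIZE = 10

CYT_GENES = ("GZMB", "PRF1")

PHENOTYPES = ("infiltrated", "excluded", "desert")


@dataclass
class SignatureScoreTable:
    """Signatures x samples score matrix plus the per-signature method tag."""

    scores: pd.DataFrame  # signatures in rows, samples in columns
    methods: dict[str, str]  # signature name -> mean_expression | rank_enrichment

    def __post_init__(self) -> None:
        for name, m in self.methods.items():
            if m not in ("mean_expression", "rank_enrichment"):
                raise ValueError(f"unknown scoring method {m!r} for signature {name!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def signature_names(self) -> list[str]:
        return list(self.scores.index)


def rank_enrichment_z(expr: ExpressionMatrix, genes: Sequence[str]) -> pd.Series:
    """Rank-sum single-sample enrichment z-score for one gene set.

    Per sample, genes are ranked within the sample (average ranks on ties)
    and the mean rank of the set members is standardized against sampling
    ``m`` of ``G`` ranks without replacement:

        z = (mean_rank - (G+1)/2) / sqrt((G-m)(G+1)/(12m))

    The score depends on expression only through within-sample ranks, so it
    is invariant to any strictly monotone per-sample transform.  This is a
    deliberately simple rank statistic with exact null moments, not a GSVA
    or ssGSEA kernel estimator.
    """
    member = expr.data.index.isin(set(genes))
    m = int(member.sum())
    G = expr.n_genes
    if m == 0:
        raise ValueError("no set genes present in expression matrix")
    if G == m:
        raise ValueError("set covers the whole matrix; enrichment undefined")
    ranks = np.apply_along_axis(rankdata, 0, expr.values)
    mean_rank = ranks[member].mean(axis=0)
    sd = np.sqrt((G - m) * (G + 1) / (12.0 * m))
    z = (mean_rank - (G + 1) / 2.0) / sd
    return pd.Series(z, index=expr.sample_ids)


def score_signatures(
    expr: ExpressionMatrix,
    sets: Sequence[GeneSet],
    mean_max_size: int = MEAN_EXPRESSION_MAX_SIZE,
) -> SignatureScoreTable:
    """Score each gene set per sample with the size-dependent rule.

    The size dispatch is evaluated on genes actually present in the
    matrix, since the score must be computable from those genes.
    """
    if expr.layer != "log2tpm1":
        raise ValueError(f"signature scoring expects log2tpm1 layer, got {expr.layer!r}")
    rows = {}
    methods = {}
    for s in sets:
        present = s.present_in(expr)
        if not present:
            raise ValueError(f"gene set {s.name!r} has no genes in the expression matrix")
        if len(present) <= mean_max_size:
            rows[s.name] = expr.data.loc[present].mean(axis=0)
            methods[s.name] = "mean_expression"
        else:
            rows[s.name] = rank_enrichment_z(expr, present)
            methods[s.name] = "rank_enrichment"
    scores = pd.DataFrame(rows).T
    scores.columns = expr.sample_ids
    return SignatureScoreTable(scores=scores, methods=methods)


def cytolytic_activity(expr: ExpressionMatrix) -> pd.Series:
    """CYT: mean log2(TPM+1) of GZMB and PRF1 per sample."""
    vals = [expr.gene(g) for g in CYT_GENES]
    return (vals[0] + vals[1]) / 2.0


class PhenotypeClassifier(ClassifierMixin, BaseEstimator):
    """Multi-class random forest for the tumor-immune phenotype.

    The phenotype (infiltrated / excluded / desert) describes the spatial
    distribution of CD8+ T cells.  The model is restricted to a
    caller-supplied gene list (the published classifier uses 157 genes
    derived from digital pathology; that list is an input, not shipped).
    """

    def __init__(
        self,
        genes: Sequence[str] | None = None,
        n_estimators: int = 200,
        random_state: int | None = None,
    ):
        self.genes = genes
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        unknown = set(np.unique(y)) - set(PHENOTYPES)
        if unknown:
            raise ValueError(
                f"unknown phenotype labels {sorted(unknown)}; expected {PHENOTYPES}"
            )
        if np.unique(y).size < 2:
            raise ValueError("phenotype training requires at least two classes")
        if isinstance(X, pd.DataFrame) and self.genes is not None:
            missing = [g for g in self.genes if g not in X.columns]
            if missing:
                raise KeyError(f"phenotype genes missing from matrix: {missing[:10]}")
            X = X[list(self.genes)]
        self.feature_names_in_ = (
            np.asarray(X.columns, dtype=object) if isinstance(X, pd.DataFrame) else None
        )
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state, n_jobs=1
        ).fit(np.asarray(X, dtype=float), y)
        self.classes_ = self.forest_.classes_
        return self

    def _subset(self, X):
        if isinstance(X, pd.DataFrame) and self.genes is not None:
            X = X[list(self.genes)]
        return np.asarray(X, dtype=float)

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(self._subset(X))

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(self._subset(X))


def train_phenotype_classifier(
    expr: ExpressionMatrix,
    phenotype_labels: dict[str, str],
    gene_list: Sequence[str],
    seed: int | None = None,
    n_estimators: int = 200,
) -> PhenotypeClassifier:
    """Fit the phenotype forest on expression restricted to ``gene_list``."""
    sub = expr.subset_genes(list(gene_list))
    missing = [s for s in sub.sample_ids if s not in phenotype_labels]
    if missing:
        raise ValueError(f"no phenotype label for samples: {missing[:5]}")
    X = pd.DataFrame(sub.values.T, index=sub.sample_ids, columns=sub.gene_ids)
    y = np.array([phenotype_labels[s] for s in sub.sample_ids])
    clf = PhenotypeClassifier(
        genes=list(gene_list), n_estimators=n_estimators, random_state=seed
    )
    return clf.fit(X, y)
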