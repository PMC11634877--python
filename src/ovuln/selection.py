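"""Consensus gene-signature selection by balanced multi-model RFE.

Three tree-ensemble families (random forest, AdaBoost, gradient boosting)
each run recursive feature elimination down to the ``top_k`` most important
genes; a gene enters the signature when at least ``min_votes`` of the three
families retain it.  Class imbalance is handled by randomly undersampling
the majority class to the minority class size before elimination, so
importance rankings are not dominated by the larger class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import RFE
from sklearn.feature_selection._base import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .matrix import ExpressionMatrix
from .truth import BRCAnessLabel

__all__ = ["SignatureSelector", "select_signature"]


def _default_families(n_estimators: int, random_state: int | None):
    return {
        "random_forest": RandomForestClassifier(
            n_estimators=n_estimators, random_state=random_state, n_jobs=1
        ),
        "adaboost": AdaBoostClassifier(
            n_estimators=n_estimators, random_state=random_state
        ),
        "gradient_boosting": GradientBoostingClassifier(
            n_estimators=n_estimators, random_state=random_state
        ),
    }


class SignatureSelector(SelectorMixin, BaseEstimator):
    """Select a consensus gene signature by balanced ensemble RFE.

    Parameters
    ----------
    top_k : int, default=50
        Number of features each model family keeps after recursive
        elimination.
    min_votes : int, default=2
        A feature is selected when it survives elimination in at least this
        many of the three families.
    step : float, default=0.2
        Fraction of remaining features eliminated per RFE iteration
        (geometric schedule).
    n_estimators : int, default=100
        Ensemble size for each family.
    random_state : int or None
        Seeds the majority-class undersampling and all three families;
        fixing it makes selection fully deterministic.

    Attributes
    ----------
    support_ : bool array of shape (n_features,)
        Consensus mask (votes >= min_votes).
    votes_ : int array of shape (n_features,)
        Number of families retaining each feature.
    family_support_ : dict of str -> bool array
        Per-family retention masks.
    signature_genes_ : list of str
        Selected feature names ordered by votes (descending) then mean RFE
        ranking (ascending).
    """

    def __init__(
        self,
        top_k: int = 50,
        min_votes: int = 2,
        step: float = 0.2,
        n_estimators: int = 100,
        random_state: int | None = None,
    ):
        self.top_k = top_k
        self.min_votes = min_votes
        self.step = step
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            feature_names = np.asarray(X.columns, dtype=object)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            feature_names = np.asarray([f"f{i}" for i in range(Xv.shape[1])], dtype=object)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("feature selection requires both classes to be present")
        if self.top_k > Xv.shape[1]:
            raise ValueError(
                f"top_k ({self.top_k}) exceeds number of candidate features ({Xv.shape[1]})"
            )
        if not 0 < self.step < 1:
            raise ValueError("step must be a fraction in (0, 1)")

        rng = np.random.default_rng(self.random_state)
        # balanced design: undersample every class to the minority size
        n_min = counts.min()
        keep_idx = np.concatenate(
            [
                rng.choice(np.flatnonzero(y == c), size=n_min, replace=False)
                for c in classes
            ]
        )
        keep_idx.sort()
        Xb, yb = Xv[keep_idx], y[keep_idx]

        votes = np.zeros(Xv.shape[1], dtype=int)
        rank_sum = np.zeros(Xv.shape[1], dtype=float)
        self.family_support_ = {}
        for name, est in _default_families(self.n_estimators, self.random_state).items():
            rfe = RFE(clone(est), n_features_to_select=self.top_k, step=self.step)
            rfe.fit(Xb, yb)
            self.family_support_[name] = rfe.support_.copy()
            votes += rfe.support_.astype(int)
            rank_sum += rfe.ranking_

        self.n_features_in_ = Xv.shape[1]
        self.feature_names_in_ = feature_names
        self.votes_ = votes
        self.mean_ranking_ = rank_sum / len(self.family_support_)
        self.support_ = votes >= self.min_votes
        order = np.lexsort(
            (feature_names.astype(str), self.mean_ranking_, -votes)
        )
        self.signature_genes_ = [
            str(feature_names[i]) for i in order if self.support_[i]
        ]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def select_signature(
    expr: ExpressionMatrix,
    labels: list[BRCAnessLabel],
    candidate_genes: list[str],
    top_k: int = 50,
    seed: int | None = None,
    **selector_kwargs,
) -> list[str]:
    """Consensus signature from an expression matrix and truth labels.

    ``candidate_genes`` restricts the search (e.g. to genes expressed in at
    least one tumor cell); all candidates must be present in ``expr``.
    """
    sub = expr.subset_genes(candidate_genes)
    by_sample = {l.sample_id: l.label for l in labels}
    missing = [s for s in sub.sample_ids if s not in by_sample]
    if missing:
        raise ValueError(f"no truth label for samples: {missing[:5]}")
    y = np.array([by_sample[s] for s in sub.sample_ids])
    X = pd.DataFrame(sub.values.T, index=sub.sample_ids, columns=sub.gene_ids)
    sel = SignatureSelector(top_k=top_k, random_state=seed, **selector_kwargs)
    sel.fit(X, y)
    return sel.signature_genes_
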