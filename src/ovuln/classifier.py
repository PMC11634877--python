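"""Random-forest BRCAness classifier with cross-validated ROC and Youden cutoff.

The classifier is trained on log2(TPM+1) expression of the consensus
signature genes.  Performance is estimated by stratified 10-fold
cross-validation; the decision cutoff is chosen by maximizing the Youden
index (sensitivity + specificity - 1) on the pooled out-of-fold
probabilities.  Classification is strict: a sample is BRCAness only when
its probability exceeds the cutoff.

Shipped defaults for applying a pre-trained model mirror the published
operating points: bulk cutoff P > 0.5266 and per-cell cutoff P > 0.45 with
sample-level majority voting over tumor cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.utils.validation import check_is_fitted

from .matrix import ExpressionMatrix
from .truth import BRCAnessLabel

__all__ = [
    "DEFAULT_BULK_CUTOFF",
    "DEFAULT_CELL_CUTOFF",
    "PUBLISHED_SIGNATURE_GENES",
    "ROCRecord",
    "youden_cutoff",
    "BRCAnessClassifier",
    "train_model",
    "classify_bulk",
    "classify_single_cell_sample",
    "save_model",
    "load_model",
]

#: published bulk decision cutoff (BRCAness iff P > 0.5266)
DEFAULT_BULK_CUTOFF = 0.5266
#: published per-cell decision cutoff for single-cell data (P > 0.45)
DEFAULT_CELL_CUTOFF = 0.45

POSITIVE = "BRCAness"
NEGATIVE = "noBRCAness"

#: The 8 publicly named members of the 24-gene BRCAness expression
#: signature.  This is a documented partial fixture: the full signature is
#: not machine-readable from public sources, so pipelines normally derive
#: their own signature with :class:`~ovuln.selection.SignatureSelector`.
PUBLISHED_SIGNATURE_GENES = (
    "CCDC90B", "CRABP2", "FZD4", "GPAA1", "PRCP", "SNRP1", "RAD17", "LTA4H",
)

MODEL_FORMAT_VERSION = 1


@dataclass
class ROCRecord:
    """ROC curve evaluated at every observed score threshold (strict > rule)."""

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float

    @classmethod
    def from_scores(cls, y_true, scores) -> "ROCRecord":
        y = np.asarray(y_true, dtype=bool)
        s = np.asarray(scores, dtype=float)
        if y.size == 0:
            raise ValueError("cannot build a ROC from empty scores")
        if not (y.any() and (~y).any()):
            raise ValueError("ROC requires both positive and negative samples")
        thresholds = np.unique(s)
        n_pos = y.sum()
        n_neg = y.size - n_pos
        sens = np.array([(s[y] > t).sum() / n_pos for t in thresholds])
        spec = np.array([(s[~y] <= t).sum() / n_neg for t in thresholds])
        return cls(thresholds, sens, spec, float(roc_auc_score(y, s)))


def youden_cutoff(roc: ROCRecord) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties are broken toward the lowest threshold, which keeps the operating
    point sensitive (calls more samples BRCAness) among equally good cuts.
    """
    if roc.thresholds.size == 0:
        raise ValueError("empty ROC record")
    j = roc.sensitivities + roc.specificities - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    return float(roc.thresholds[best[0]])


class BRCAnessClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest BRCAness vs noBRCAness classifier.

    Parameters
    ----------
    n_estimators : int, default=200
        Trees in the forest.
    n_folds : int, default=10
        Stratified cross-validation folds used for the ROC estimate and
        the pooled out-of-fold cutoff search.
    cutoff : "youden" or float, default="youden"
        Decision cutoff for bulk classification.  "youden" selects the
        cutoff on pooled out-of-fold probabilities; a float fixes it (e.g.
        the published 0.5266 operating point).
    cell_cutoff : float, default=0.45
        Per-cell cutoff for single-cell classification.
    random_state : int or None
        Seeds the forest and the fold shuffling.

    Attributes
    ----------
    classes_ : array of class labels
    forest_ : fitted RandomForestClassifier
    cutoff_ : float, decision cutoff actually in force
    roc_ : ROCRecord from pooled out-of-fold probabilities
    cv_auc_mean_, cv_auc_sd_ : per-fold AUC mean and standard deviation
    oof_proba_ : pooled out-of-fold BRCAness probabilities (training order)
    """

    def __init__(
        self,
        n_estimators: int = 200,
        n_folds: int = 10,
        cutoff: str | float = "youden",
        cell_cutoff: float = DEFAULT_CELL_CUTOFF,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.n_folds = n_folds
        self.cutoff = cutoff
        self.cell_cutoff = cell_cutoff
        self.random_state = random_state

    def _positive_index(self) -> int:
        # positive class is "BRCAness" for string labels, else the larger label
        classes = list(self.classes_)
        if POSITIVE in classes:
            return classes.index(POSITIVE)
        return len(classes) - 1

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError(f"expected exactly two classes, got {list(classes)}")
        if counts.min() < self.n_folds:
            small = classes[counts.argmin()]
            raise ValueError(
                f"class {small!r} has {counts.min()} samples, fewer than "
                f"n_folds={self.n_folds}; reduce n_folds or enlarge the cohort"
            )
        if not (isinstance(self.cutoff, str) and self.cutoff == "youden"):
            c = float(self.cutoff)
            if not 0.0 < c < 1.0:
                raise ValueError(f"cutoff must be in (0, 1), got {c}")
        self.classes_ = classes

        forest = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state, n_jobs=1
        )
        cv = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.random_state
        )
        proba = cross_val_predict(forest, Xv, y, cv=cv, method="predict_proba")
        pos = self._positive_index()
        y_bin = y == classes[pos]
        self.oof_proba_ = proba[:, pos]

        fold_aucs = []
        for _, test_idx in cv.split(Xv, y):
            fold_aucs.append(roc_auc_score(y_bin[test_idx], self.oof_proba_[test_idx]))
        self.cv_auc_mean_ = float(np.mean(fold_aucs))
        self.cv_auc_sd_ = float(np.std(fold_aucs))
        self.roc_ = ROCRecord.from_scores(y_bin, self.oof_proba_)

        if isinstance(self.cutoff, str) and self.cutoff == "youden":
            self.cutoff_ = youden_cutoff(self.roc_)
        else:
            self.cutoff_ = float(self.cutoff)

        self.forest_ = forest.fit(Xv, y)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return self.forest_.predict_proba(X)

    def brcaness_probability(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, self._positive_index()]

    def predict(self, X):
        """BRCAness iff probability strictly exceeds the cutoff."""
        p = self.brcaness_probability(X)
        pos = self.classes_[self._positive_index()]
        neg = self.classes_[1 - self._positive_index()]
        return np.where(p > self.cutoff_, pos, neg)


def _expr_to_X(
    expr: ExpressionMatrix, genes: Sequence[str], impute_missing: str | None
) -> pd.DataFrame:
    present = set(expr.gene_ids)
    missing = [g for g in genes if g not in present]
    if missing:
        if impute_missing == "zero":
            warnings.warn(
                f"imputing {len(missing)} missing signature genes with zeros: "
                f"{missing[:10]}",
                stacklevel=3,
            )
            data = expr.data.reindex(list(genes)).fillna(0.0)
            return pd.DataFrame(data.to_numpy().T, index=expr.sample_ids, columns=list(genes))
        raise KeyError(f"signature genes missing from expression matrix: {missing}")
    sub = expr.subset_genes(list(genes))
    return pd.DataFrame(sub.values.T, index=sub.sample_ids, columns=list(genes))


def train_model(
    expr: ExpressionMatrix,
    labels: Sequence[BRCAnessLabel],
    signature_genes: Sequence[str],
    n_folds: int = 10,
    seed: int | None = None,
    cutoff: str | float = "youden",
    n_estimators: int = 200,
) -> BRCAnessClassifier:
    """Train the forest on the signature genes with CV ROC and Youden cutoff."""
    X = _expr_to_X(expr, signature_genes, impute_missing=None)
    by_sample = {l.sample_id: l.label for l in labels}
    missing = [s for s in X.index if s not in by_sample]
    if missing:
        raise ValueError(f"no truth label for samples: {missing[:5]}")
    y = np.array([by_sample[s] for s in X.index])
    clf = BRCAnessClassifier(
        n_estimators=n_estimators, n_folds=n_folds, cutoff=cutoff, random_state=seed
    )
    return clf.fit(X, y)


def classify_bulk(
    model: BRCAnessClassifier,
    expr: ExpressionMatrix,
    impute_missing: str | None = None,
) -> pd.DataFrame:
    """Per-sample BRCAness probability and label (strict P > cutoff)."""
    genes = [str(g) for g in model.feature_names_in_]
    X = _expr_to_X(expr, genes, impute_missing)
    p = model.brcaness_probability(X)
    return pd.DataFrame(
        {
            "sample_id": X.index,
            "brcaness_probability": p,
            "brcaness_label": np.where(p > model.cutoff_, POSITIVE, NEGATIVE),
        }
    ).set_index("sample_id")


def classify_single_cell_sample(
    model: BRCAnessClassifier,
    cell_expr: ExpressionMatrix,
    sample_of_cell: Mapping[str, str],
    cell_cutoff: float | None = None,
    impute_missing: str | None = None,
) -> pd.DataFrame:
    """Sample-level BRCAness by majority vote over per-cell calls.

    Each cell is BRCAness when its probability strictly exceeds the cell
    cutoff (default 0.45); a sample is BRCAness when strictly more than
    half of its cells are.  An exact half split is noBRCAness ("majority"
    read strictly — conservative for treatment selection).
    """
    cutoff = model.cell_cutoff if cell_cutoff is None else float(cell_cutoff)
    unmapped = [c for c in cell_expr.sample_ids if c not in sample_of_cell]
    if unmapped:
        raise ValueError(f"cells with no sample assignment: {unmapped[:5]}")
    genes = [str(g) for g in model.feature_names_in_]
    X = _expr_to_X(cell_expr, genes, impute_missing)
    p = model.brcaness_probability(X)
    cells = pd.DataFrame(
        {
            "sample_id": [sample_of_cell[c] for c in X.index],
            "positive": p > cutoff,
        },
        index=X.index,
    )
    grouped = cells.groupby("sample_id")["positive"].agg(["size", "sum"])
    if (grouped["size"] == 0).any():
        raise ValueError("sample with zero cells")
    out = pd.DataFrame(
        {
            "n_cells": grouped["size"].astype(int),
            "n_brcaness_cells": grouped["sum"].astype(int),
        }
    )
    out["brcaness_cell_fraction"] = out["n_brcaness_cells"] / out["n_cells"]
    out["brcaness_label"] = np.where(
        out["n_brcaness_cells"] * 2 > out["n_cells"], POSITIVE, NEGATIVE
    )
    out.index.name = "sample_id"
    return out


def save_model(model: BRCAnessClassifier, path) -> None:
    """Serialize a trained model (gene list, cutoffs, seed, forest)."""
    check_is_fitted(model, "forest_")
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "signature_genes": [str(g) for g in model.feature_names_in_],
        "bulk_cutoff": model.cutoff_,
        "cell_cutoff": model.cell_cutoff,
        "random_state": model.random_state,
        "cv_auc_mean": model.cv_auc_mean_,
        "cv_auc_sd": model.cv_auc_sd_,
        "estimator": model,
    }
    joblib.dump(payload, path)


def load_model(path) -> BRCAnessClassifier:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    return payload["estimator"]
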