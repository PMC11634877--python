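"""Combination-immunotherapy vulnerability scoring.

Three steps, all on log2(TPM+1) expression:

1. CYT-to-C1QA ratio = 0.5 * (GZMB + PRF1) / C1QA — the balance between
   cytotoxic lymphocyte activity and suppressive tumor-associated
   macrophages (C1QA as surrogate marker).
2. C2C = 1 / (1 + exp(-(ratio - location) / scale)) — a logistic squash of
   the ratio to (0, 1); shipped parameters location=0.301, scale=0.0433.
3. Vulnerability score = w_brca * BRCAness probability + w_c2c * C2C;
   shipped weights 2.597 and 1.166 were learned by logistic regression of
   combination-therapy response on a BRCAness proxy and C2C.

Refitting is supported: ``fit_c2c_params`` maps a reference cohort's
quartiles onto C2C 0.25/0.75, and ``fit_vulnerability_weights`` refits the
logistic slopes on a response-annotated cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .matrix import ExpressionMatrix
from .immune import cytolytic_activity

__all__ = [
    "C2CParams",
    "VulnerabilityWeights",
    "VulnerabilityResult",
    "cyt_to_c1qa_ratio",
    "c2c_transform",
    "vulnerability_score",
    "fit_c2c_params",
    "fit_vulnerability_weights",
    "compute_vulnerability",
    "vulnerability_map",
]


@dataclass(frozen=True)
class C2CParams:
    """Location/scale of the logistic C2C transform (midpoint at location)."""

    location: float = 0.301
    scale: float = 0.0433

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")


@dataclass(frozen=True)
class VulnerabilityWeights:
    """Slope weights of the vulnerability score."""

    w_brca: float = 2.597
    w_c2c: float = 1.166

    def __post_init__(self) -> None:
        if not (np.isfinite(self.w_brca) and np.isfinite(self.w_c2c)):
            raise ValueError("weights must be finite")


@dataclass
class VulnerabilityResult:
    sample_id: str
    brcaness_probability: float
    cyt: float
    c1qa: float
    ratio: float
    c2c: float
    score: float


def cyt_to_c1qa_ratio(expr: ExpressionMatrix) -> pd.Series:
    """0.5 * (GZMB + PRF1) / C1QA on log2(TPM+1) values, per sample.

    Samples with C1QA exactly zero get NaN (undefined ratio) with a
    warning rather than an infinite score.
    """
    cyt = cytolytic_activity(expr)
    c1qa = expr.gene("C1QA").astype(float)
    zero = c1qa == 0
    if zero.any():
        warnings.warn(
            f"C1QA is zero for samples {list(c1qa.index[zero])[:5]}; "
            "CYT-to-C1QA ratio undefined (NaN)",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = cyt / c1qa
    ratio[zero] = np.nan
    return ratio


def c2c_transform(ratio, params: C2CParams = C2CParams()):
    """Logistic transform of the ratio to (0, 1); 0.5 at ratio == location."""
    r = np.asarray(ratio, dtype=float)
    out = expit((r - params.location) / params.scale)
    if out.ndim == 0:
        return float(out)
    if isinstance(ratio, pd.Series):
        return pd.Series(out, index=ratio.index)
    return out


def vulnerability_score(
    brca_prob, c2c, weights: VulnerabilityWeights = VulnerabilityWeights()
):
    """Weighted sum w_brca * BRCAness probability + w_c2c * C2C."""
    p = np.asarray(brca_prob, dtype=float)
    c = np.asarray(c2c, dtype=float)
    for name, v in (("brca_prob", p), ("c2c", c)):
        valid = np.isnan(v) | ((v >= 0.0) & (v <= 1.0))
        if not valid.all():
            raise ValueError(f"{name} must lie in [0, 1]")
    out = weights.w_brca * p + weights.w_c2c * c
    if out.ndim == 0:
        return float(out)
    if isinstance(brca_prob, pd.Series):
        return pd.Series(out, index=brca_prob.index)
    return out


def fit_c2c_params(cohort_ratios: Sequence[float]) -> C2CParams:
    """Fit the C2C transform so the cohort quartiles map to 0.25 and 0.75.

    location = (q1 + q3) / 2 (midhinge), scale = IQR / (2 ln 3).  With the
    logistic form, expit(+-ln 3) = 0.75 / 0.25, so the fitted transform
    sends q1 -> 0.25 and q3 -> 0.75 exactly.  For symmetric cohorts the
    midhinge coincides with the median.
    """
    r = np.asarray(cohort_ratios, dtype=float)
    r = r[np.isfinite(r)]
    if r.size < 10:
        raise ValueError(f"need >= 10 finite ratios to fit C2C parameters, got {r.size}")
    q1, q3 = np.quantile(r, [0.25, 0.75])
    iqr = q3 - q1
    if iqr <= 0:
        raise ValueError("degenerate cohort: inter-quartile range is zero")
    return C2CParams(location=(q1 + q3) / 2.0, scale=iqr / (2.0 * np.log(3.0)))


def fit_vulnerability_weights(
    brca_proxy: Sequence[float],
    c2c: Sequence[float],
    response: Sequence[int],
) -> VulnerabilityWeights:
    """Refit the score weights by logistic regression of therapy response.

    Fits response ~ intercept + brca_proxy + c2c by maximum likelihood and
    returns the two slopes (the intercept is fitted but discarded, matching
    the interceptless form of the score).  On perfect separation the MLE
    diverges; the fit then falls back to a ridge-penalized logistic
    regression with a warning.
    """
    import statsmodels.api as sm

    proxy = np.asarray(brca_proxy, dtype=float)
    c = np.asarray(c2c, dtype=float)
    y = np.asarray(response, dtype=float)
    if proxy.shape != c.shape or proxy.shape != y.shape:
        raise ValueError("brca_proxy, c2c and response must have equal length")
    if np.unique(y).size < 2:
        raise ValueError("response must contain both classes")
    X = np.column_stack([proxy, c])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # separation surfaces as a warning
            fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        params = fit.params
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e4:
            raise RuntimeError("unstable logistic fit")
        return VulnerabilityWeights(w_brca=float(params[1]), w_c2c=float(params[2]))
    except Exception:
        from sklearn.linear_model import LogisticRegression

        warnings.warn(
            "logistic MLE unstable (perfect or quasi-perfect separation); "
            "falling back to ridge-penalized fit",
            stacklevel=2,
        )
        lr = LogisticRegression(C=1.0, solver="lbfgs").fit(X, y.astype(int))
        return VulnerabilityWeights(
            w_brca=float(lr.coef_[0, 0]), w_c2c=float(lr.coef_[0, 1])
        )


def compute_vulnerability(
    expr: ExpressionMatrix,
    brcaness_probability: pd.Series,
    params: C2CParams = C2CParams(),
    weights: VulnerabilityWeights = VulnerabilityWeights(),
) -> pd.DataFrame:
    """Full per-sample vulnerability table from expression and probabilities."""
    cyt = cytolytic_activity(expr)
    c1qa = expr.gene("C1QA").astype(float)
    ratio = cyt_to_c1qa_ratio(expr)
    c2c = c2c_transform(ratio, params)
    prob = brcaness_probability.reindex(cyt.index)
    if prob.isna().any():
        raise ValueError(
            f"missing BRCAness probability for samples: "
            f"{list(prob.index[prob.isna()])[:5]}"
        )
    score = vulnerability_score(prob, c2c, weights)
    return pd.DataFrame(
        {
            "brcaness_probability": prob,
            "cyt": cyt,
            "c1qa": c1qa,
            "ratio": ratio,
            "c2c": c2c,
            "vulnerability_score": score,
        }
    )


def vulnerability_map(
    results: pd.DataFrame,
    grid_n: int = 50,
    weights: VulnerabilityWeights = VulnerabilityWeights(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample points plus a background score lattice for the 2-D map.

    Returns ``(points, lattice)``: points carry x=c2c, y=brcaness
    probability and the sample's score; the lattice evaluates the score on
    a grid_n x grid_n grid over the unit square for color-coding.
    """
    points = pd.DataFrame(
        {
            "sample_id": results.index,
            "c2c": results["c2c"].to_numpy(),
            "brcaness_probability": results["brcaness_probability"].to_numpy(),
            "vulnerability_score": results["vulnerability_score"].to_numpy(),
        }
    )
    axis = np.linspace(0.0, 1.0, grid_n)
    xx, yy = np.meshgrid(axis, axis)
    lattice = pd.DataFrame(
        {
            "x": xx.ravel(),
            "y": yy.ravel(),
            "score": vulnerability_score(yy.ravel(), xx.ravel(), weights),
        }
    )
    return points, lattice
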