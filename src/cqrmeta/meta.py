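"""Random-effects meta-regression of quantile effect estimates on (q, q^2).

The model is y_q = b0 + b1*q + b2*q^2 + u + e, with e ~ N(0, se_q^2) and
u ~ N(0, tau2).  Fixed effects are estimated by weighted least squares with
weights 1/(se_q^2 + tau2); tau2 by REML Fisher scoring with a
DerSimonian-Laird fallback.  Estimates at different quantiles are treated as
independent (the observed type-I inflation this causes is corrected
empirically by genomic control downstream).

Note: b0 is the extrapolated intercept at q = 0, not a marginal effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .regression import QuantileEffectSet, QuantileGrid

Z975 = stats.norm.ppf(0.975)

REML_MAX_ITER = 100
REML_TOL = 1e-8


@dataclass
class MetaRegResult:
    """Fitted 3-coefficient quantile-profile model for one variant.

    Arrays are indexed 0, 1, 2 for the intercept, linear, and quadratic
    coefficients.  ``corrected`` flags genomic-control adjustment.
    """

    variant_id: str
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    z: np.ndarray
    p: np.ndarray
    tau2: float
    cov: np.ndarray
    method: str = "reml"
    corrected: bool = False

    def __post_init__(self):
        if self.tau2 < 0:
            raise ValidationError("tau2 must be non-negative")

    @property
    def beta0(self) -> float:
        return float(self.beta[0])

    @property
    def beta1(self) -> float:
        return float(self.beta[1])

    @property
    def beta2(self) -> float:
        return float(self.beta[2])


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ y)
    return beta, cov


def _tau2_dl(X: np.ndarray, y: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian-Laird moment estimator generalized to moderators."""
    k, p = X.shape
    w = 1.0 / v
    beta, cov = _wls(X, y, w)
    resid = y - X @ beta
    Q = float(np.sum(w * resid**2))
    XtW = X.T * w
    XtW2 = X.T * w**2
    trace_term = float(np.sum(w) - np.trace(np.linalg.inv(XtW @ X) @ (XtW2 @ X)))
    if trace_term <= 0:
        return 0.0
    return max(0.0, (Q - (k - p)) / trace_term)


def _reml_fisher_scoring(X: np.ndarray, y: np.ndarray, v: np.ndarray):
    """REML tau2 via Fisher scoring; returns (tau2, converged)."""
    tau2 = max(_tau2_dl(X, y, v), 1e-8)
    for _ in range(REML_MAX_ITER):
        w = 1.0 / (v + tau2)
        _, cov = _wls(X, y, w)
        WX = X * w[:, None]
        P = np.diag(w) - WX @ cov @ WX.T
        Py = P @ y
        score = 0.5 * (float(Py @ Py) - float(np.trace(P)))
        info = 0.5 * float(np.sum(P * P))  # tr(P P)
        if info <= 0:
            return tau2, False
        step = score / info
        new = max(0.0, tau2 + step)
        if abs(new - tau2) < REML_TOL * (1.0 + tau2):
            return new, True
        tau2 = new
    return tau2, False


def fit_meta_regression(
    effects: QuantileEffectSet, method: str = "reml"
) -> MetaRegResult:
    """Fit b0 + b1*q + b2*q^2 to (beta_q, se_q) with REML heterogeneity.

    Requires at least 4 usable quantile records and strictly positive
    standard errors.
    """
    ok = effects.ok & np.isfinite(effects.betas) & np.isfinite(effects.ses)
    q = effects.quantiles[ok]
    y = effects.betas[ok]
    se = effects.ses[ok]
    if len(y) < 4:
        raise ValidationError(
            f"need >= 4 usable quantile records, got {len(y)}"
        )
    if np.any(se <= 0):
        raise ValidationError("all se_q must be > 0")
    X = np.column_stack([np.ones_like(q), q, q**2])
    v = se**2

    if method == "fixed":
        tau2, used = 0.0, "fixed"
    elif method == "dl":
        tau2, used = _tau2_dl(X, y, v), "dl"
    elif method == "reml":
        tau2, converged = _reml_fisher_scoring(X, y, v)
        used = "reml"
        if not converged:
            tau2, used = _tau2_dl(X, y, v), "dl_fallback"
    else:
        raise ValidationError(f"unknown method {method!r}")

    w = 1.0 / (v + tau2)
    beta, cov = _wls(X, y, w)
    se_b = np.sqrt(np.diag(cov))
    z = beta / se_b
    p = 2.0 * stats.norm.sf(np.abs(z))
    return MetaRegResult(
        variant_id=effects.variant_id,
        beta=beta,
        se=se_b,
        ci_low=beta - Z975 * se_b,
        ci_high=beta + Z975 * se_b,
        z=z,
        p=p,
        tau2=float(tau2),
        cov=cov,
        method=used,
    )


def predict_profile(res: MetaRegResult, grid: QuantileGrid):
    """Predicted effect b0 + b1*q + b2*q^2 with delta-method 95% CI.

    Returns (q, fit, ci_low, ci_high) arrays.
    """
    q = grid.array
    X = np.column_stack([np.ones_like(q), q, q**2])
    fit = X @ res.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, res.cov, X))
    return q, fit, fit - Z975 * se, fit + Z975 * se


def bonferroni_threshold(
    alpha_family: float, n_variants: int, n_coef: int = 3
) -> float:
    """Family-wise threshold alpha / (n_coef * n_variants)."""
    if n_variants < 1 or n_coef < 1:
        raise ValidationError("n_variants and n_coef must be >= 1")
    return alpha_family / (n_coef * n_variants)


def classify_uniformity(
    res: MetaRegResult,
    alpha_family: float,
    n_variants: int,
    n_coef: int = 3,
) -> str:
    """Classify a profile by its non-uniformity coefficients (b1, b2).

    'bonferroni_significant' if min(p1, p2) clears the family threshold,
    'nominal' if it clears 0.05, else 'uniform'.
    """
    p1, p2 = res.p[1], res.p[2]
    if not (np.isfinite(p1) and np.isfinite(p2)):
        raise ValidationError("p-values missing for beta1/beta2")
    pmin = min(p1, p2)
    if pmin < bonferroni_threshold(alpha_family, n_variants, n_coef):
        return "bonferroni_significant"
    if pmin < 0.05:
        return "nominal"
    return "uniform"
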