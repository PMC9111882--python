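"""Random-effects pooling of change-score estimates.

The model is the standard normal-normal random-effects model

    d_i = mu + u_i + e_i,    u_i ~ N(0, tau^2),   e_i ~ N(0, se_i^2)

with known within-study variances se_i^2.  The between-study variance tau^2
is estimated by restricted maximum likelihood (REML, the default) or by the
DerSimonian-Laird moment estimator; the pooled effect is the inverse-variance
weighted mean with weights 1/(se_i^2 + tau^2), and inference uses Wald
z-statistics on the pooled scale.

The same machinery handles an arbitrary fixed-effect design matrix X, which
is what the moderator meta-regressions and the regression-based funnel
asymmetry test build on: REML here profiles out all of beta, not just the
intercept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .effects import ChangeScoreEstimate

__all__ = [
    "MetaResult",
    "LeaveOneOutResult",
    "MetaAnalysisError",
    "estimate_tau2",
    "restricted_loglik",
    "fit_random_effects",
    "heterogeneity",
    "leave_one_out",
    "wls_fit",
]

#: Two-sided 95% normal quantile used for all Wald intervals.
Z_CRIT = float(stats.norm.ppf(0.975))

_REML_TOL = 1e-8
_REML_MAX_ITER = 200

TauMethod = Literal["REML", "DL"]


class MetaAnalysisError(ValueError):
    """Raised for designs the random-effects model cannot be fitted to."""


@dataclass
class MetaResult:
    """Pooled result for one subset of estimates."""

    subset_label: str
    k: int
    n_studies: int
    pooled: float
    se_pooled: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    tau2: float
    Q: float
    Q_p: float
    I2: float
    I2_q: float  # secondary (Q - df)/Q definition
    method: str = "REML"
    weights: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "weights"}
        return d


@dataclass
class LeaveOneOutResult:
    """Refit with one estimate omitted, plus influence flags."""

    omitted_id: str
    result: MetaResult
    outside_full_ci: bool
    significance_changed: bool


# ---------------------------------------------------------------------------
# tau^2 estimation with a general design matrix
# ---------------------------------------------------------------------------


def _wls_core(y: np.ndarray, w: np.ndarray, X: np.ndarray):
    """Weighted LS pieces: beta, (X'WX)^-1, residuals."""
    XtW = X.T * w
    A = XtW @ X
    Ainv = np.linalg.inv(A)
    beta = Ainv @ (XtW @ y)
    resid = y - X @ beta
    return beta, Ainv, A, resid


def restricted_loglik(tau2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """Restricted log-likelihood of tau^2 (additive constants dropped)."""
    w = 1.0 / (v + tau2)
    _, _, A, resid = _wls_core(y, w, X)
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    return -0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * resid**2))


def _reml_score_info(tau2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray):
    """REML score and Fisher information for tau^2 via the P matrix."""
    w = 1.0 / (v + tau2)
    _, Ainv, _, resid = _wls_core(y, w, X)
    Xw = X * w[:, None]  # W X
    B = X.T @ (Xw * w[:, None])  # X' W^2 X
    C = X.T @ (Xw * (w**2)[:, None])  # X' W^3 X
    tr_P = np.sum(w) - np.trace(Ainv @ B)
    tr_P2 = np.sum(w**2) - 2.0 * np.trace(Ainv @ C) + np.trace(Ainv @ B @ Ainv @ B)
    Py = w * resid
    yPPy = float(np.sum(Py**2))
    score = -0.5 * (tr_P - yPPy)
    info = 0.5 * tr_P2
    return score, info


def estimate_tau2(
    y: np.ndarray,
    v: np.ndarray,
    X: np.ndarray | None = None,
    method: TauMethod = "REML",
) -> float:
    """Estimate the between-study variance tau^2.

    REML uses Fisher scoring with non-negativity projection (tolerance 1e-8,
    at most 200 iterations), falling back to a bounded maximisation of the
    restricted log-likelihood if scoring fails to converge.  DL is the
    closed-form moment estimator generalised to an arbitrary design.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if X is None:
        X = np.ones((len(y), 1))
    X = np.asarray(X, dtype=float)
    k, p = X.shape
    if k < p + 1:
        raise MetaAnalysisError(f"need at least {p + 1} estimates for {p} coefficients")
    if np.any(v <= 0):
        raise MetaAnalysisError("all sampling variances must be positive")

    if method == "DL":
        w0 = 1.0 / v
        _, Ainv0, _, resid0 = _wls_core(y, w0, X)
        QE = float(np.sum(w0 * resid0**2))
        B0 = X.T @ ((X * w0[:, None]) * w0[:, None])
        tr_P0 = float(np.sum(w0) - np.trace(Ainv0 @ B0))
        if tr_P0 <= 0:
            return 0.0
        return max(0.0, (QE - (k - p)) / tr_P0)

    if method != "REML":
        raise ValueError(f"unknown tau^2 method {method!r}")

    # Fisher scoring, started from the DL estimate
    tau2 = estimate_tau2(y, v, X, method="DL")
    converged = False
    for _ in range(_REML_MAX_ITER):
        score, info = _reml_score_info(tau2, y, v, X)
        if info <= 0:
            break
        step = score / info
        new = tau2 + step
        if new < 0.0:
            new = 0.0
        # step halving when the restricted likelihood would decrease
        ll_old = restricted_loglik(tau2, y, v, X)
        halvings = 0
        while restricted_loglik(new, y, v, X) < ll_old and halvings < 30:
            new = tau2 + (new - tau2) / 2.0
            halvings += 1
        if abs(new - tau2) < _REML_TOL * max(1.0, tau2):
            tau2 = new
            converged = True
            break
        tau2 = new
    if converged:
        if tau2 <= _REML_TOL:
            # verify boundary: score must be non-positive at 0
            score0, _ = _reml_score_info(0.0, y, v, X)
            if score0 <= 0:
                return 0.0
        else:
            return tau2
    # fallback: bounded scalar maximisation of the restricted log-likelihood
    upper = max(10.0 * float(np.var(y)), 10.0 * float(np.max(v)), 1e-4)
    res = optimize.minimize_scalar(
        lambda t2: -restricted_loglik(t2, y, v, X),
        bounds=(0.0, upper),
        method="bounded",
        options={"xatol": 1e-12},
    )
    tau2_opt = float(res.x)
    if restricted_loglik(0.0, y, v, X) >= restricted_loglik(tau2_opt, y, v, X):
        return 0.0
    return max(0.0, tau2_opt)


def wls_fit(
    y: np.ndarray, v: np.ndarray, X: np.ndarray, tau2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted LS coefficients and covariance at a given tau^2."""
    w = 1.0 / (np.asarray(v, float) + tau2)
    beta, Ainv, _, _ = _wls_core(np.asarray(y, float), w, np.asarray(X, float))
    return beta, Ainv


# ---------------------------------------------------------------------------
# Pooling, heterogeneity, leave-one-out
# ---------------------------------------------------------------------------


def _check_estimates(estimates: Sequence[ChangeScoreEstimate], k_min: int) -> None:
    if len(estimates) < k_min:
        raise MetaAnalysisError(
            f"need at least {k_min} estimates, got {len(estimates)}"
        )
    degenerate = [e.estimate_id for e in estimates if e.se <= 0.0]
    if degenerate:
        raise MetaAnalysisError(
            "zero-variance estimates must be filtered before pooling: "
            + ", ".join(degenerate)
        )


def heterogeneity(
    y: np.ndarray, v: np.ndarray, tau2: float
) -> tuple[float, float, float, float]:
    """Cochran's Q, its p-value, and I^2 (tau^2-based primary, Q-based secondary).

    Q uses fixed-effect weights 1/se_i^2 around the fixed-effect mean.  The
    primary I^2 is 100 * tau^2 / (tau^2 + s^2) with the typical within-study
    variance s^2 = (k-1) * sum(w) / ((sum(w))^2 - sum(w^2)); the secondary
    definition is 100 * max(0, Q - df) / Q.
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    k = len(y)
    w = 1.0 / v
    mean_fe = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - mean_fe) ** 2))
    df = k - 1
    Q_p = float(stats.chi2.sf(Q, df)) if df > 0 else float("nan")
    sw, sw2 = float(np.sum(w)), float(np.sum(w**2))
    s2 = df * sw / (sw * sw - sw2) if sw * sw > sw2 else float("nan")
    I2 = 100.0 * tau2 / (tau2 + s2) if (tau2 + s2) > 0 else 0.0
    I2_q = 100.0 * max(0.0, Q - df) / Q if Q > 0 else 0.0
    return Q, Q_p, I2, I2_q


def fit_random_effects(
    estimates: Sequence[ChangeScoreEstimate],
    method: TauMethod = "REML",
    subset_label: str = "",
) -> MetaResult:
    """Fit the random-effects model to a set of change-score estimates.

    Requires k >= 2 estimates, all with positive sampling variance (use
    :func:`drinkmeta.effects.filter_degenerate` first).
    """
    _check_estimates(estimates, k_min=2)
    y = np.array([e.d for e in estimates])
    v = np.array([e.var for e in estimates])
    tau2 = estimate_tau2(y, v, method=method)
    w = 1.0 / (v + tau2)
    sw = float(np.sum(w))
    pooled = float(np.sum(w * y) / sw)
    se_pooled = sw**-0.5
    z = pooled / se_pooled
    p = 2.0 * float(stats.norm.sf(abs(z)))
    Q, Q_p, I2, I2_q = heterogeneity(y, v, tau2)
    return MetaResult(
        subset_label=subset_label,
        k=len(estimates),
        n_studies=len({e.study_id for e in estimates}),
        pooled=pooled,
        se_pooled=se_pooled,
        ci_low=pooled - Z_CRIT * se_pooled,
        ci_high=pooled + Z_CRIT * se_pooled,
        z=z,
        p=p,
        tau2=tau2,
        Q=Q,
        Q_p=Q_p,
        I2=I2,
        I2_q=I2_q,
        method=method,
        weights=list(100.0 * w / sw),
    )


def leave_one_out(
    estimates: Sequence[ChangeScoreEstimate],
    method: TauMethod = "REML",
    alpha: float = 0.05,
) -> list[LeaveOneOutResult]:
    """Refit the model k times, omitting one estimate each.

    An omission is flagged when the reduced-model pooled estimate falls
    outside the full-model confidence interval, or when it flips the
    significance of the pooled effect at ``alpha``.
    """
    _check_estimates(estimates, k_min=3)
    full = fit_random_effects(estimates, method=method)
    full_sig = full.p < alpha
    out: list[LeaveOneOutResult] = []
    for i, omitted in enumerate(estimates):
        reduced = [e for j, e in enumerate(estimates) if j != i]
        fit = fit_random_effects(
            reduced, method=method, subset_label=f"loo:-{omitted.estimate_id}"
        )
        outside = not (full.ci_low <= fit.pooled <= full.ci_high)
        flipped = (fit.p < alpha) != full_sig
        out.append(LeaveOneOutResult(omitted.estimate_id, fit, outside, flipped))
    return out
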