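"""Small-study-bias diagnostics: Egger's regression-based test, funnel data.

The primary variant regresses the change score on its standard error inside
the mixed-effects meta-regression framework (the standard-error-as-moderator
formulation used by metafor's ``regtest`` default), with tau^2 re-estimated
by REML under the bias model; the slope's t statistic on k - 2 degrees of
freedom tests funnel asymmetry.  A classical weighted-least-squares variant
(no random effect) is provided for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import ChangeScoreEstimate
from .random_effects import (
    MetaAnalysisError,
    MetaResult,
    TauMethod,
    Z_CRIT,
    estimate_tau2,
    wls_fit,
)

__all__ = ["EggerResult", "egger_test", "funnel_data"]

EggerVariant = Literal["re_moderator", "classical"]


@dataclass
class EggerResult:
    """Egger regression-based asymmetry test."""

    t: float
    df: int
    p: float
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    tau2: float
    variant: str

    @property
    def asymmetric(self) -> bool:
        return self.p < 0.05

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["asymmetric"] = self.asymmetric
        return d


def egger_test(
    estimates: Sequence[ChangeScoreEstimate],
    variant: EggerVariant = "re_moderator",
    tau_method: TauMethod = "REML",
) -> EggerResult:
    """Test funnel-plot asymmetry by regressing effect size on its SE.

    Requires k >= 3 estimates with unequal standard errors.  The reported
    statistic is t = slope / SE(slope) on k - 2 degrees of freedom; p < 0.05
    flags asymmetry (small studies reporting systematically different
    effects than large ones).
    """
    k = len(estimates)
    if k < 3:
        raise MetaAnalysisError(f"Egger test needs at least 3 estimates, got {k}")
    y = np.array([e.d for e in estimates])
    se = np.array([e.se for e in estimates])
    if np.any(se <= 0):
        raise MetaAnalysisError("zero-variance estimates must be filtered first")
    if np.ptp(se) < 1e-12:
        raise MetaAnalysisError("all standard errors equal; Egger predictor degenerate")
    v = se**2
    X = np.column_stack([np.ones(k), se])

    if variant == "re_moderator":
        tau2 = estimate_tau2(y, v, X, method=tau_method)
        beta, cov = wls_fit(y, v, X, tau2)
        se_beta = np.sqrt(np.diag(cov))
    elif variant == "classical":
        # classical Egger: WLS of d on se with weights 1/se^2 and the
        # residual scale estimated, equivalent to OLS of d/se on 1/se
        tau2 = 0.0
        beta, cov_u = wls_fit(y, v, X, 0.0)
        resid = y - X @ beta
        s2 = float(np.sum(resid**2 / v) / (k - 2))
        cov = cov_u * s2
        se_beta = np.sqrt(np.diag(cov))
    else:
        raise ValueError(f"unknown Egger variant {variant!r}")

    t = float(beta[1] / se_beta[1])
    df = k - 2
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return EggerResult(
        t=t,
        df=df,
        p=p,
        slope=float(beta[1]),
        slope_se=float(se_beta[1]),
        intercept=float(beta[0]),
        intercept_se=float(se_beta[0]),
        tau2=tau2,
        variant=variant,
    )


def funnel_data(
    estimates: Sequence[ChangeScoreEstimate],
    fit: MetaResult,
    n_contour: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready funnel tables: one row per estimate, plus pseudo-CI contours.

    The contour frame traces pooled +/- 1.96 * se over the observed SE range
    (collapsing to the pooled estimate at se = 0), the usual funnel guide
    lines under the fixed-effect sampling model.
    """
    points = pd.DataFrame(
        {
            "estimate_id": [e.estimate_id for e in estimates],
            "d": [e.d for e in estimates],
            "se": [e.se for e in estimates],
        }
    )
    se_max = float(points["se"].max()) if len(points) else 0.0
    se_grid = np.linspace(0.0, se_max * 1.05 if se_max > 0 else 1.0, n_contour)
    contours = pd.DataFrame(
        {
            "se": se_grid,
            "center": fit.pooled,
            "low": fit.pooled - Z_CRIT * se_grid,
            "high": fit.pooled + Z_CRIT * se_grid,
        }
    )
    return points, contours
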