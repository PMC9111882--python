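"""Single-moderator mixed-effects meta-regressions.

Each moderator (survey timing period, age-profile oversampling, use of
sampling weights, European sub-region) is entered alone as a categorical
fixed effect:

    d_i = X_i beta + u_i + e_i,   u_i ~ N(0, tau^2),  e_i ~ N(0, se_i^2)

with dummy coding against a stated reference level, residual tau^2 by REML,
and an omnibus Wald chi-square test (QM) on all non-intercept coefficients.
Because the four moderator models reuse the same estimates, significance is
judged against a Bonferroni-corrected threshold (0.05 / 4 = 0.0125 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import ChangeScoreEstimate
from .random_effects import (
    MetaAnalysisError,
    TauMethod,
    Z_CRIT,
    estimate_tau2,
    heterogeneity,
    wls_fit,
)

__all__ = [
    "MetaRegressionResult",
    "REFERENCE_LEVELS",
    "bonferroni_alpha",
    "fit_meta_regression",
]

#: Default reference level per moderator (the timing comparison is against
#: the first pandemic period, March-June 2020).
REFERENCE_LEVELS = {
    "period": "P1",
    "age_profile": "general",
    "weighted": False,
    "sub_region": "Western",
    "convenience_sample": False,
}

#: Number of moderator models fitted on the same estimates.
N_MODERATOR_MODELS = 4


@dataclass
class MetaRegressionResult:
    """Coefficients, omnibus test and level means for one moderator model."""

    moderator: str
    reference_level: str
    levels: list[str]
    coefficients: pd.DataFrame  # term, estimate, se, z, p, ci_low, ci_high
    level_means: pd.DataFrame  # level, estimate, se, ci_low, ci_high
    QM: float
    QM_df: int
    QM_p: float
    tau2_residual: float
    Q_residual: float
    I2_residual: float
    k: int
    alpha_corrected: float
    method: str = "REML"
    dropped_levels: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.QM_p < self.alpha_corrected

    def to_dict(self) -> dict:
        return {
            "moderator": self.moderator,
            "reference_level": self.reference_level,
            "levels": self.levels,
            "coefficients": self.coefficients.to_dict("records"),
            "level_means": self.level_means.to_dict("records"),
            "QM": self.QM,
            "QM_df": self.QM_df,
            "QM_p": self.QM_p,
            "tau2_residual": self.tau2_residual,
            "Q_residual": self.Q_residual,
            "I2_residual": self.I2_residual,
            "k": self.k,
            "alpha_corrected": self.alpha_corrected,
            "significant": self.significant,
            "method": self.method,
            "dropped_levels": self.dropped_levels,
        }


def bonferroni_alpha(alpha: float = 0.05, m: int = N_MODERATOR_MODELS) -> float:
    """Bonferroni-corrected significance threshold alpha / m."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of models must be >= 1, got {m}")
    return alpha / m


def _design_matrix(
    values: list, reference: str
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design with intercept; returns (X, ordered levels)."""
    levels = sorted({str(v) for v in values})
    ref = str(reference)
    if ref in levels:
        levels.remove(ref)
        levels = [ref] + levels
    k = len(values)
    X = np.ones((k, len(levels)))
    for j, level in enumerate(levels[1:], start=1):
        X[:, j] = [1.0 if str(v) == level else 0.0 for v in values]
    return X, levels


def fit_meta_regression(
    estimates: Sequence[ChangeScoreEstimate],
    moderator: str,
    reference_level: str | None = None,
    method: TauMethod = "REML",
    alpha: float = 0.05,
    n_models: int = N_MODERATOR_MODELS,
) -> MetaRegressionResult:
    """Fit a single-moderator random-effects meta-regression.

    Parameters
    ----------
    estimates
        Change-score estimates carrying the moderator in their
        ``moderators`` mapping.
    moderator
        Covariate name (``period``, ``age_profile``, ``weighted``,
        ``sub_region``, ...).
    reference_level
        Level absorbed into the intercept; defaults per
        :data:`REFERENCE_LEVELS`.

    Raises
    ------
    MetaAnalysisError
        If the moderator is constant across estimates or there are too few
        estimates for the number of levels.
    """
    if not estimates:
        raise MetaAnalysisError("no estimates supplied")
    y = np.array([e.d for e in estimates])
    v = np.array([e.var for e in estimates])
    if moderator is None:
        # intercept-only model: identical to the plain random-effects fit
        values = [""] * len(estimates)
        reference_level = ""
        X, levels = np.ones((len(estimates), 1)), [""]
    else:
        values = []
        for e in estimates:
            if moderator not in e.moderators:
                raise MetaAnalysisError(
                    f"estimate {e.estimate_id} lacks moderator {moderator!r}"
                )
            values.append(e.moderators[moderator])
        if reference_level is None:
            reference_level = REFERENCE_LEVELS.get(moderator, str(values[0]))
        observed = sorted({str(v) for v in values})
        if len(observed) < 2:
            raise MetaAnalysisError(
                f"moderator {moderator!r} is constant ({observed[0]!r}); no contrast to fit"
            )
        if str(reference_level) not in observed:
            # the stated reference did not survive subsetting; fall back
            reference_level = observed[0]
        X, levels = _design_matrix(values, str(reference_level))
    k, p = X.shape
    if k < p + 1:
        raise MetaAnalysisError(
            f"need at least {p + 1} estimates for {p} coefficient(s), got {k}"
        )

    tau2 = estimate_tau2(y, v, X, method=method)
    beta, cov = wls_fit(y, v, X, tau2)
    se_beta = np.sqrt(np.diag(cov))
    zval = beta / se_beta
    pval = 2.0 * stats.norm.sf(np.abs(zval))

    terms = ["intercept"] + [f"{moderator}[{lv}]" for lv in levels[1:]]
    coefficients = pd.DataFrame(
        {
            "term": terms,
            "estimate": beta,
            "se": se_beta,
            "z": zval,
            "p": pval,
            "ci_low": beta - Z_CRIT * se_beta,
            "ci_high": beta + Z_CRIT * se_beta,
        }
    )

    # omnibus Wald chi-square on the non-intercept coefficients
    QM_df = p - 1
    if QM_df > 0:
        bs = beta[1:]
        cov_s = cov[1:, 1:]
        QM = float(bs @ np.linalg.solve(cov_s, bs))
        QM_p = float(stats.chi2.sf(QM, QM_df))
    else:
        QM, QM_p = 0.0, float("nan")

    # fitted mean per level: L beta with L the level indicator contrasts
    rows = []
    for j, level in enumerate(levels):
        L = np.zeros(p)
        L[0] = 1.0
        if j > 0:
            L[j] = 1.0
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        rows.append(
            {
                "level": level,
                "estimate": est,
                "se": se,
                "ci_low": est - Z_CRIT * se,
                "ci_high": est + Z_CRIT * se,
                "k": int(sum(str(val) == level for val in values)),
            }
        )
    level_means = pd.DataFrame(rows)

    # residual heterogeneity around the moderator model
    w0 = 1.0 / v
    beta0, _ = wls_fit(y, v, X, 0.0)
    Q_res = float(np.sum(w0 * (y - X @ beta0) ** 2))
    _, _, I2_res, _ = heterogeneity(y, v, tau2)

    return MetaRegressionResult(
        moderator=moderator,
        reference_level=str(reference_level),
        levels=levels,
        coefficients=coefficients,
        level_means=level_means,
        QM=QM,
        QM_df=QM_df,
        QM_p=QM_p,
        tau2_residual=tau2,
        Q_residual=Q_res,
        I2_residual=I2_res,
        k=k,
        alpha_corrected=bonferroni_alpha(alpha, n_models),
        method=method,
    )
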