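"""Synthetic study-level datasets with the structure the analysis assumes.

Each simulated survey draws its drinkers' responses from a three-cell
multinomial (increase, decrease, no change).  The study-specific truth is
parameterised on the change-score scale: with overall churn c (the expected
share of drinkers reporting any change) and true study effect theta,

    p_inc = (c + theta) / 2,    p_dec = (c - theta) / 2

so that E[d] = theta and p_inc + p_dec = c.  Study effects are
theta_i = mu + moderator shifts + N(0, tau^2): a grand mean, additive
categorical moderator effects, and between-study heterogeneity.  Optional
extras emulate surveys that report drinking starters/stoppers and a
selection (suppression) mechanism for funnel-asymmetry experiments.

Default parameter values mirror the study conditions of the European
COVID-19 drinking-change literature this pipeline targets: 44 surveys,
mostly fielded March-June 2020, a grand-mean change score of -0.038,
heterogeneity large enough to put I^2 near 99%, and survey sizes spanning
a few hundred to tens of thousands of drinkers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import random_effects
from .bias import egger_test
from .effects import compute_effects, filter_degenerate
from .moderators import bonferroni_alpha, fit_meta_regression
from .study_io import (
    AgeProfile,
    Design,
    Indicator,
    Period,
    Population,
    Stratum,
    StudyRecord,
    SubRegion,
    prepare_records,
)

__all__ = ["SyntheticConfig", "ConfigError", "generate_studies", "recovery_experiment"]

logger = logging.getLogger(__name__)

#: Implied cell probabilities may be clipped by at most this much before the
#: configuration is rejected outright.
CLIP_TOLERANCE = 0.01

_DEFAULT_PREVALENCE: dict[str, dict] = {
    # ~3 in 4 surveys fielded in the first pandemic period
    "period": {"P1": 0.75, "P2": 0.15, "P3": 0.10},
    "age_profile": {"general": 0.70, "younger": 0.20, "older": 0.10},
    # just under half of the surveys applied sampling weights
    "weighted": {False: 0.55, True: 0.45},
    "sub_region": {"Northern": 0.20, "Western": 0.40, "Southern": 0.25, "Eastern": 0.15},
    "convenience_sample": {False: 0.48, True: 0.52},
}


class ConfigError(ValueError):
    """The synthetic configuration implies invalid cell probabilities."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study generator.

    Attributes
    ----------
    k
        Number of studies.
    mu
        True grand-mean change score (reference moderator levels).
    tau
        Between-study SD of the true change score.
    churn
        Expected share of drinkers reporting any change, p_inc + p_dec.
    n_range
        (min, max) drinkers per study; sizes are log-uniform.
    moderator_effects
        ``{moderator: {level: shift}}`` additive effects on the change score.
    moderator_prevalence
        ``{moderator: {level: probability}}`` category frequencies.
    start_stop_rate
        Optional (f_start, f_stop): expected starters/stoppers as fractions
        of the drinker denominator, reported separately on the record.
    selection_bias
        Optional retention probability ``f(d, se) -> [0, 1]``; studies are
        resampled until k are retained (funnel suppression experiments).
    seed
        Seed for the generator; identical seeds give identical datasets.
    """

    k: int = 44
    mu: float = -0.038
    tau: float = 0.14
    churn: float = 0.5
    n_range: tuple[int, int] = (300, 20_000)
    moderator_effects: Mapping[str, Mapping] = field(default_factory=dict)
    moderator_prevalence: Mapping[str, Mapping] = field(default_factory=dict)
    start_stop_rate: tuple[float, float] | None = None
    selection_bias: Callable[[float, float], float] | None = None
    indicator: Indicator = Indicator.OVERALL_USE
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if not (0.0 < self.churn <= 1.0):
            raise ConfigError(f"churn={self.churn} outside (0, 1]")
        if abs(self.mu) + 3.0 * self.tau > self.churn + 1e-12:
            raise ConfigError(
                f"|mu| + 3 tau = {abs(self.mu) + 3 * self.tau:.3f} exceeds "
                f"churn = {self.churn}; implied probabilities leave the simplex"
            )
        if self.n_range[0] < 1 or self.n_range[1] < self.n_range[0]:
            raise ConfigError(f"invalid n_range {self.n_range}")

    def prevalences(self) -> dict[str, dict]:
        merged = {k: dict(v) for k, v in _DEFAULT_PREVALENCE.items()}
        for mod, probs in self.moderator_prevalence.items():
            merged[mod] = dict(probs)
        return merged


_MODERATOR_FIELDS = {
    "period": ("period", Period),
    "age_profile": ("age_profile", AgeProfile),
    "weighted": ("weighted", None),
    "sub_region": ("sub_region", SubRegion),
    "convenience_sample": ("convenience_sample", None),
}


def _draw_moderators(rng: np.random.Generator, prevalences: Mapping[str, Mapping]) -> dict:
    out = {}
    for mod, probs in prevalences.items():
        levels = list(probs.keys())
        p = np.array([probs[lv] for lv in levels], dtype=float)
        p = p / p.sum()
        out[mod] = levels[rng.choice(len(levels), p=p)]
    return out


def generate_studies(config: SyntheticConfig) -> list[StudyRecord]:
    """Generate one synthetic dataset of study records.

    Deterministic given ``config.seed``.  The emitted records always pass
    study-table validation and carry the drawn moderators; counts satisfy
    n_inc + n_dec + n_same = n_drinkers by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    prevalences = config.prevalences()
    log_lo, log_hi = np.log(config.n_range[0]), np.log(config.n_range[1])
    records: list[StudyRecord] = []
    attempts = 0
    max_attempts = 1000 * config.k
    clipped = 0
    while len(records) < config.k:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigError(
                "selection_bias retains too few studies; cannot reach k"
            )
        i = len(records)
        mods = _draw_moderators(rng, prevalences)
        # systematic violations are a config error; rare tail draws of the
        # study effect are clipped to the simplex with a warning
        det = config.mu
        for mod, shifts in config.moderator_effects.items():
            for key, shift in shifts.items():
                if str(key) == str(mods.get(mod)):
                    det += shift
        if (config.churn - abs(det)) / 2.0 < -CLIP_TOLERANCE:
            raise ConfigError(
                f"moderator level combination implies systematic probability "
                f"{(config.churn - abs(det)) / 2.0:.3f} below the simplex "
                "beyond clipping tolerance"
            )
        theta = det + rng.normal(0.0, config.tau)
        if abs(theta) > config.churn:
            clipped += 1
            theta = float(np.clip(theta, -config.churn, config.churn))
        p_inc = (config.churn + theta) / 2.0
        p_dec = (config.churn - theta) / 2.0
        n = int(np.exp(rng.uniform(log_lo, log_hi)))
        n_inc, n_dec, _ = rng.multinomial(n, [p_inc, p_dec, 1.0 - p_inc - p_dec])
        rec = StudyRecord(
            study_id=f"S{i + 1:03d}",
            estimate_id=f"S{i + 1:03d}:{config.indicator.value}:total",
            country="XX",
            sub_region=SubRegion(mods["sub_region"]),
            period=Period(mods["period"]),
            design=Design.CROSS_SECTIONAL,
            population=Population.GENERAL,
            stratum=Stratum.TOTAL,
            indicator=config.indicator,
            n_total=n,
            weighted=bool(mods["weighted"]),
            age_profile=AgeProfile(mods["age_profile"]),
            convenience_sample=bool(mods["convenience_sample"]),
            n_drinkers=n,
            n_inc=int(n_inc),
            n_dec=int(n_dec),
        )
        if config.start_stop_rate is not None:
            f_start, f_stop = config.start_stop_rate
            rec.n_start = int(rng.binomial(n, min(f_start, 1.0)))
            rec.n_stop = int(rng.binomial(n, min(f_stop, 1.0)))
        if config.indicator is Indicator.PREVALENCE and config.start_stop_rate is None:
            # prevalence studies must report either discordant counts or
            # marginal prevalences; derive the latter from a baseline
            base = rng.uniform(0.5, 0.8)
            rec.p_before = base
            rec.p_during = float(np.clip(base + theta, 0.0, 1.0))
            rec.n_inc = rec.n_dec = None
        if config.selection_bias is not None:
            d = (int(n_inc) - int(n_dec)) / n
            se = np.sqrt(max(int(n_inc) + int(n_dec) - n * d * d, 0.0)) / n
            if rng.uniform() > config.selection_bias(d, se):
                continue
        records.append(rec)
    if clipped:
        warnings.warn(
            f"{clipped} of {attempts} studies had implied probabilities "
            "clipped to the simplex",
            stacklevel=2,
        )
    errors = [e for r in records for e in r.validate()]
    assert not errors, f"generator produced invalid records: {errors}"
    return records


def _marginal_truth(config: SyntheticConfig) -> float:
    """Population-average true change score implied by the configuration."""
    mu = config.mu
    prevalences = config.prevalences()
    for mod, shifts in config.moderator_effects.items():
        probs = prevalences.get(mod, {})
        total = sum(probs.values()) or 1.0
        for key, shift in shifts.items():
            for lv, pr in probs.items():
                if str(lv) == str(key):
                    mu += shift * pr / total
    return mu


def recovery_experiment(
    config: SyntheticConfig,
    replicates: int = 200,
    seed: int | None = None,
    moderator: str = "period",
    alpha: float = 0.05,
    n_models: int = 4,
    tau_method: random_effects.TauMethod = "REML",
) -> pd.DataFrame:
    """Run the full pipeline on many synthetic datasets and summarise it.

    For each replicate the generator's records are prepared, converted to
    effect sizes, pooled by REML (or DL), and the timing meta-regression and
    Egger test are run.  The summary reports bias, RMSE and 95% CI coverage
    for the pooled change score, mean tau^2, and the rejection rates of the
    moderator omnibus test (at the Bonferroni-corrected threshold) and the
    Egger test (at 0.05) — the type-I error rates under a null
    configuration, power otherwise.
    """
    if replicates < 50:
        raise ValueError("recovery_experiment needs at least 50 replicates")
    truth = _marginal_truth(config)
    alpha_corr = bonferroni_alpha(alpha, n_models)
    base = np.random.SeedSequence(seed if seed is not None else config.seed)
    sub_seeds = base.generate_state(replicates)
    rows = []
    for r in range(replicates):
        cfg = SyntheticConfig(**{**config.__dict__, "seed": int(sub_seeds[r])})
        records = prepare_records(generate_studies(cfg))
        kept, _ = filter_degenerate(compute_effects(records))
        fit = random_effects.fit_random_effects(kept, method=tau_method)
        row = {
            "replicate": r,
            "pooled": fit.pooled,
            "tau2": fit.tau2,
            "covered": fit.ci_low <= truth <= fit.ci_high,
            "Q": fit.Q,
            "I2": fit.I2,
        }
        try:
            mr = fit_meta_regression(
                kept, moderator, alpha=alpha, n_models=n_models, method=tau_method
            )
            row["moderator_reject"] = mr.QM_p < alpha_corr
        except random_effects.MetaAnalysisError:
            row["moderator_reject"] = np.nan
        try:
            eg = egger_test(kept)
            row["egger_reject"] = eg.p < alpha
            row["egger_t"] = eg.t
        except random_effects.MetaAnalysisError:
            row["egger_reject"] = np.nan
            row["egger_t"] = np.nan
        rows.append(row)
    reps = pd.DataFrame(rows)
    summary = pd.DataFrame(
        [
            {
                "truth": truth,
                "replicates": replicates,
                "mean_pooled": reps["pooled"].mean(),
                "bias": reps["pooled"].mean() - truth,
                "rmse": float(np.sqrt(((reps["pooled"] - truth) ** 2).mean())),
                "coverage": reps["covered"].mean(),
                "mean_tau2": reps["tau2"].mean(),
                "median_tau2": reps["tau2"].median(),
                "mean_Q": reps["Q"].mean(),
                "mean_I2": reps["I2"].mean(),
                "moderator_rejection_rate": reps["moderator_reject"].mean(),
                "egger_rejection_rate": reps["egger_reject"].mean(),
            }
        ]
    )
    summary.attrs["replicates_frame"] = reps
    return summary
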