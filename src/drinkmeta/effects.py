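"""Per-study effect sizes: the paired-proportion change score and its SE.

The change score of a survey is

    d = (n_inc - n_dec) / n

where ``n_inc`` and ``n_dec`` are the numbers of current drinkers reporting
an increase and a decrease in their alcohol use, and ``n`` is the number of
current drinkers.  Because both proportions are measured on the same
respondents, the sampling variance of d follows the multinomial model

    SE = (1/n) * sqrt( n_inc + n_dec - (n_inc - n_dec)^2 / n )

which is the delta-method standard error of the difference of two paired
proportions.  Prevalence-of-use changes reuse the same formulas, either on
discordant (started/stopped) counts or, when only marginal prevalences are
reported, on the proportion-scale analogue (flagged as an approximation
because the pairing information is lost).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .study_io import Indicator, StudyRecord

__all__ = [
    "ChangeScoreEstimate",
    "EffectSizeError",
    "change_score",
    "prevalence_difference",
    "compute_effects",
    "filter_degenerate",
    "effects_table",
]

logger = logging.getLogger(__name__)


class EffectSizeError(ValueError):
    """Raised for inconsistent or insufficient inputs to an effect size."""


@dataclass
class ChangeScoreEstimate:
    """A single effect size entering the meta-analysis."""

    estimate_id: str
    d: float
    se: float
    n: int
    study_id: str = ""
    moderators: dict = field(default_factory=dict)
    approximate_se: bool = False  # marginal-prevalence substitution used

    @property
    def var(self) -> float:
        return self.se * self.se


def change_score(
    n: int,
    n_inc: int,
    n_dec: int,
    estimate_id: str = "",
    study_id: str = "",
    moderators: dict | None = None,
) -> ChangeScoreEstimate:
    """Paired-proportion change score with its closed-form standard error.

    Parameters
    ----------
    n
        Number of current drinkers (the denominator).
    n_inc, n_dec
        Respondents reporting an increase / a decrease.

    Raises
    ------
    EffectSizeError
        If ``n`` is zero or ``n_inc + n_dec`` exceeds ``n``.
    """
    if n < 1:
        raise EffectSizeError("change score undefined for n = 0")
    if n_inc < 0 or n_dec < 0:
        raise EffectSizeError("counts must be non-negative")
    if n_inc + n_dec > n:
        raise EffectSizeError(f"n_inc + n_dec = {n_inc + n_dec} exceeds n = {n}")
    diff = n_inc - n_dec
    d = diff / n
    inner = n_inc + n_dec - diff * diff / n
    se = math.sqrt(max(inner, 0.0)) / n
    return ChangeScoreEstimate(
        estimate_id=estimate_id,
        d=d,
        se=se,
        n=n,
        study_id=study_id or estimate_id,
        moderators=dict(moderators or {}),
    )


def prevalence_difference(
    n: int,
    n_start: int | None = None,
    n_stop: int | None = None,
    p_before: float | None = None,
    p_during: float | None = None,
    estimate_id: str = "",
    study_id: str = "",
    moderators: dict | None = None,
) -> ChangeScoreEstimate:
    """Before/during difference in the prevalence of alcohol use.

    With discordant counts (respondents who started or stopped drinking) the
    paired change-score formulas apply directly with
    ``(n_inc, n_dec) := (n_start, n_stop)``.  With only marginal prevalences
    the difference is ``p_during - p_before`` and the SE uses the
    proportion-scale form ``sqrt((p_during + p_before - d^2) / n)``; the
    resulting estimate is flagged ``approximate_se`` because the discordant
    cells are unobserved.
    """
    if n_start is not None and n_stop is not None:
        est = change_score(
            n, n_start, n_stop,
            estimate_id=estimate_id, study_id=study_id, moderators=moderators,
        )
        return est
    if p_before is not None and p_during is not None:
        if n < 1:
            raise EffectSizeError("prevalence difference undefined for n = 0")
        d = p_during - p_before
        inner = p_during + p_before - d * d
        se = math.sqrt(max(inner, 0.0) / n)
        est = ChangeScoreEstimate(
            estimate_id=estimate_id,
            d=d,
            se=se,
            n=n,
            study_id=study_id or estimate_id,
            moderators=dict(moderators or {}),
            approximate_se=True,
        )
        return est
    raise EffectSizeError(
        "prevalence difference needs (n_start, n_stop) or (p_before, p_during)"
    )


def _moderators_of(record: StudyRecord) -> dict:
    return {
        "period": record.period.value,
        "age_profile": record.age_profile.value,
        "weighted": bool(record.weighted),
        "sub_region": record.sub_region.value,
        "convenience_sample": bool(record.convenience_sample),
    }


def compute_effects(records: Iterable[StudyRecord]) -> list[ChangeScoreEstimate]:
    """Map prepared study records to change-score estimates.

    Records with the prevalence indicator are routed to
    :func:`prevalence_difference`; all others to :func:`change_score`.
    """
    out: list[ChangeScoreEstimate] = []
    for rec in records:
        mods = _moderators_of(rec)
        if rec.indicator is Indicator.PREVALENCE:
            n = rec.n_drinkers or rec.n_total
            if n is None:
                raise EffectSizeError(f"{rec.estimate_id}: no denominator available")
            est = prevalence_difference(
                n,
                n_start=rec.n_start,
                n_stop=rec.n_stop,
                p_before=rec.p_before,
                p_during=rec.p_during,
                estimate_id=rec.estimate_id,
                study_id=rec.study_id,
                moderators=mods,
            )
        else:
            if rec.n_drinkers is None or rec.n_inc is None or rec.n_dec is None:
                raise EffectSizeError(
                    f"{rec.estimate_id}: n_drinkers, n_inc and n_dec are required"
                )
            est = change_score(
                rec.n_drinkers,
                rec.n_inc,
                rec.n_dec,
                estimate_id=rec.estimate_id,
                study_id=rec.study_id,
                moderators=mods,
            )
        out.append(est)
    return out


def filter_degenerate(
    estimates: Sequence[ChangeScoreEstimate],
) -> tuple[list[ChangeScoreEstimate], list[ChangeScoreEstimate]]:
    """Split off estimates with zero sampling variance.

    A change score has SE = 0 when no respondent reported any change or when
    every changer moved in the same direction and |d| = 1.  Such estimates
    cannot enter inverse-variance pooling; they are returned separately and
    logged.
    """
    kept, dropped = [], []
    for est in estimates:
        (dropped if est.se <= 0.0 else kept).append(est)
    for est in dropped:
        logger.warning(
            "estimate %s has zero sampling variance (d=%.3f); excluded from pooling",
            est.estimate_id, est.d,
        )
    return kept, dropped


def effects_table(estimates: Sequence[ChangeScoreEstimate]) -> pd.DataFrame:
    """Effects as a flat table (estimate_id, d, se, n, moderators)."""
    rows = []
    for e in estimates:
        row = {
            "estimate_id": e.estimate_id,
            "study_id": e.study_id,
            "d": e.d,
            "se": e.se,
            "n": e.n,
            "approximate_se": e.approximate_se,
        }
        row.update(e.moderators)
        rows.append(row)
    return pd.DataFrame(rows)
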