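"""End-to-end orchestration: validate -> effects -> subsets -> pooling ->
moderators -> bias diagnostics -> leave-one-out, with a machine-readable
report bundle.

Outputs are deterministic for identical inputs and configuration: the JSON
report carries no timestamps and all tables are written in a fixed order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .bias import egger_test, funnel_data
from .effects import compute_effects, effects_table, filter_degenerate
from .moderators import bonferroni_alpha, fit_meta_regression
from .random_effects import (
    MetaAnalysisError,
    fit_random_effects,
    leave_one_out,
)
from .study_io import (
    Schema,
    Subset,
    build_subsets,
    prepare_records,
    read_studies,
    validation_report,
    write_studies,
)

__all__ = ["RunConfig", "EligibilityError", "run_pipeline", "analyse_subset"]

logger = logging.getLogger(__name__)

#: Moderators entered (one at a time) in the meta-regressions.
MODERATORS = ("period", "age_profile", "weighted", "sub_region")


class EligibilityError(ValueError):
    """An explicitly requested subset has fewer than five independent studies."""


@dataclass
class RunConfig:
    """Analytic choices for one pipeline run."""

    input: str | Path
    outdir: str | Path = "drinkmeta_out"
    schema: Schema = field(default_factory=Schema)
    tau_method: str = "REML"
    egger_variant: str = "re_moderator"
    alpha: float = 0.05
    n_moderators: int = 4
    subsets: list[str] | None = None  # None: all eligible subsets
    sensitivity_no_convenience: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


def analyse_subset(subset: Subset, config: RunConfig) -> dict:
    """All analyses for one eligible subset; returns a JSON-ready mapping."""
    estimates = compute_effects(subset.records)
    kept, dropped = filter_degenerate(estimates)
    out: dict = {
        "label": subset.label,
        "k": len(kept),
        "n_studies": subset.n_studies,
        "dropped_zero_variance": [e.estimate_id for e in dropped],
    }
    fit = fit_random_effects(kept, method=config.tau_method, subset_label=subset.label)
    out["meta"] = fit.to_dict()
    out["moderators"] = {}
    for mod in MODERATORS:
        try:
            mr = fit_meta_regression(
                kept,
                mod,
                method=config.tau_method,
                alpha=config.alpha,
                n_models=config.n_moderators,
            )
            out["moderators"][mod] = mr.to_dict()
        except MetaAnalysisError as exc:
            out["moderators"][mod] = {"error": str(exc)}
    try:
        eg = egger_test(kept, variant=config.egger_variant, tau_method=config.tau_method)
        out["egger"] = eg.to_dict()
    except MetaAnalysisError as exc:
        out["egger"] = {"error": str(exc)}
    try:
        loo = leave_one_out(kept, method=config.tau_method, alpha=config.alpha)
        out["leave_one_out"] = {
            "influential": [
                r.omitted_id
                for r in loo
                if r.outside_full_ci or r.significance_changed
            ],
            "results": [
                {
                    "omitted": r.omitted_id,
                    "pooled": r.result.pooled,
                    "ci_low": r.result.ci_low,
                    "ci_high": r.result.ci_high,
                    "p": r.result.p,
                    "I2": r.result.I2,
                    "outside_full_ci": r.outside_full_ci,
                    "significance_changed": r.significance_changed,
                }
                for r in loo
            ],
        }
    except MetaAnalysisError as exc:
        out["leave_one_out"] = {"error": str(exc)}
    out["_objects"] = {"estimates": kept, "fit": fit}
    return out


def _forest_table(analysis: dict) -> pd.DataFrame:
    ests = analysis["_objects"]["estimates"]
    fit = analysis["_objects"]["fit"]
    from .random_effects import Z_CRIT

    return pd.DataFrame(
        {
            "estimate_id": [e.estimate_id for e in ests],
            "d": [e.d for e in ests],
            "ci_low": [e.d - Z_CRIT * e.se for e in ests],
            "ci_high": [e.d + Z_CRIT * e.se for e in ests],
            "weight_pct": fit.weights,
        }
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to ``outdir``.

    Returns the report mapping (also written as ``report.json``).  Files per
    subset: forest-plot table, funnel table, leave-one-out table.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = read_studies(config.input, schema=config.schema)
    records = prepare_records(records)
    write_studies(records, outdir / "validated_studies.csv")
    (outdir / "validation_report.json").write_text(
        json.dumps(validation_report(), indent=2, sort_keys=True)
    )

    subsets = build_subsets(records)
    if config.sensitivity_no_convenience:
        for s in list(subsets):
            if s.label == "overall/total":
                kept = [r for r in s.records if not r.convenience_sample]
                n_studies = len({r.study_id for r in kept})
                subsets.append(
                    Subset("overall/total/no-convenience", kept, n_studies >= 5)
                )
    requested = set(config.subsets) if config.subsets else None
    if requested:
        by_label = {s.label: s for s in subsets}
        unknown = requested - set(by_label)
        if unknown:
            raise EligibilityError(f"unknown subset(s): {sorted(unknown)}")
        for lbl in sorted(requested):
            s = by_label[lbl]
            if not s.eligible:
                raise EligibilityError(
                    f"subset {lbl!r} has only {s.n_studies} independent studies "
                    "(five required)"
                )

    report: dict = {
        "tool": "drinkmeta",
        "version": __version__,
        "config": {
            "input": str(config.input),
            "tau_method": config.tau_method,
            "egger_variant": config.egger_variant,
            "alpha": config.alpha,
            "n_moderators": config.n_moderators,
            "alpha_corrected": bonferroni_alpha(config.alpha, config.n_moderators),
            "seed": config.seed,
        },
        "subsets": {},
        "ineligible_subsets": {},
    }
    for s in subsets:
        if requested is not None and s.label not in requested:
            continue
        if not s.eligible:
            report["ineligible_subsets"][s.label] = {
                "n_studies": s.n_studies,
                "k": s.k,
            }
            continue
        analysis = analyse_subset(s, config)
        objs = analysis.pop("_objects")
        report["subsets"][s.label] = analysis

        tag = s.label.replace("/", "_")
        _forest_table({"_objects": objs}).to_csv(
            outdir / f"forest_{tag}.csv", index=False
        )
        effects_table(objs["estimates"]).to_csv(
            outdir / f"effects_{tag}.csv", index=False
        )
        points, contours = funnel_data(objs["estimates"], objs["fit"])
        points.to_csv(outdir / f"funnel_{tag}.csv", index=False)
        contours.to_csv(outdir / f"funnel_contours_{tag}.csv", index=False)

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=True)
    )
    return report
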