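"""Reading, validation and preparation of study-level survey records.

Each record describes one estimate from one survey: how many of its current
drinkers reported increasing or decreasing their alcohol use (or, for the
prevalence indicator, drinking prevalence before and during the observation
window), together with the covariates used downstream as moderators.

Preparation steps implemented here:

* reconstruction of the drinker denominator from the total sample size and
  the proportion of current drinkers (and of women/men for stratified rows);
* folding respondents who started or stopped drinking into the
  increase/decrease counts and the denominator;
* collapsing monthly survey waves into the three pre-defined pandemic
  periods (March-June 2020, July-September 2020, October 2020 or later);
* grouping records into analysis subsets, with the >= 5 independent-studies
  eligibility gate.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Period",
    "Design",
    "Population",
    "Stratum",
    "Indicator",
    "AgeProfile",
    "SubRegion",
    "StudyRecord",
    "MonthlyWave",
    "Subset",
    "Schema",
    "ValidationError",
    "SchemaError",
    "read_studies",
    "write_studies",
    "validation_report",
    "estimate_drinker_n",
    "fold_start_stop",
    "average_periods",
    "build_subsets",
    "prepare_records",
    "MIN_INDEPENDENT_STUDIES",
]

#: Minimum number of independent studies for a subset to be pooled.
MIN_INDEPENDENT_STUDIES = 5


class Period(str, enum.Enum):
    """Pre-defined pandemic periods used as the timing moderator."""

    P1 = "P1"  # March-June 2020
    P2 = "P2"  # July-September 2020
    P3 = "P3"  # October 2020 or later


class Design(str, enum.Enum):
    CROSS_SECTIONAL = "cross-sectional"
    REPEATED_CROSS_SECTIONAL = "repeated cross-sectional"
    LONGITUDINAL = "longitudinal"


class Population(str, enum.Enum):
    GENERAL = "general"
    AUD = "AUD"


class Stratum(str, enum.Enum):
    TOTAL = "total"
    WOMEN = "women"
    MEN = "men"


class Indicator(str, enum.Enum):
    OVERALL_USE = "overall_use"
    FREQUENCY = "frequency"
    QUANTITY = "quantity"
    HED = "HED"
    PREVALENCE = "prevalence"


class AgeProfile(str, enum.Enum):
    GENERAL = "general"
    YOUNGER = "younger"  # at least half of the sample <= 35 y
    OLDER = "older"  # at least half of the sample >= 50 y


class SubRegion(str, enum.Enum):
    NORTHERN = "Northern"
    WESTERN = "Western"
    SOUTHERN = "Southern"
    EASTERN = "Eastern"


class ValidationError(ValueError):
    """A record (or file row) violates the schema invariants."""


class SchemaError(ValueError):
    """The input file lacks mandatory columns or has unparseable cells."""


def _round_half_up(x: float) -> int:
    # reconstructed denominators and counts must stay integers
    return int(math.floor(x + 0.5))


@dataclass
class StudyRecord:
    """One study x stratum x indicator row of the extraction table."""

    study_id: str
    estimate_id: str
    country: str = ""
    sub_region: SubRegion = SubRegion.WESTERN
    period: Period = Period.P1
    design: Design = Design.CROSS_SECTIONAL
    population: Population = Population.GENERAL
    stratum: Stratum = Stratum.TOTAL
    indicator: Indicator = Indicator.OVERALL_USE
    n_total: int | None = None
    prop_drinkers: float | None = None
    prop_women: float | None = None
    weighted: bool = False
    age_profile: AgeProfile = AgeProfile.GENERAL
    convenience_sample: bool = False
    n_drinkers: int | None = None
    n_inc: int | None = None
    n_dec: int | None = None
    n_start: int | None = None
    n_stop: int | None = None
    p_inc: float | None = None
    p_dec: float | None = None
    p_before: float | None = None
    p_during: float | None = None
    provenance: dict = field(default_factory=dict)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        errors: list[str] = []
        for name in ("n_total", "n_drinkers", "n_inc", "n_dec", "n_start", "n_stop"):
            v = getattr(self, name)
            if v is not None and (v < 0 or v != int(v)):
                errors.append(f"{name}={v} must be a non-negative integer")
        for name in ("prop_drinkers", "prop_women", "p_inc", "p_dec", "p_before", "p_during"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                errors.append(f"{name}={v} outside [0, 1]")
        if (
            self.n_drinkers is not None
            and self.n_inc is not None
            and self.n_dec is not None
            and self.n_inc + self.n_dec > self.n_drinkers
        ):
            errors.append(
                f"n_inc + n_dec = {self.n_inc + self.n_dec} exceeds n_drinkers={self.n_drinkers}"
            )
        if self.indicator is Indicator.PREVALENCE:
            has_prev = self.p_before is not None and self.p_during is not None
            has_counts = self.n_start is not None and self.n_stop is not None
            if not (has_prev or has_counts):
                errors.append(
                    "prevalence indicator requires (p_before, p_during) or (n_start, n_stop)"
                )
        return errors


@dataclass
class MonthlyWave:
    """One monthly wave of a study reporting change proportions each month."""

    study_id: str
    month: str  # ISO "YYYY-MM"
    n_drinkers: int
    p_inc: float
    p_dec: float

    def validate(self) -> list[str]:
        errors = []
        if not (0.0 <= self.p_inc <= 1.0 and 0.0 <= self.p_dec <= 1.0):
            errors.append("p_inc/p_dec outside [0, 1]")
        if self.p_inc + self.p_dec > 1.0 + 1e-12:
            errors.append(f"p_inc + p_dec = {self.p_inc + self.p_dec:.4f} exceeds 1")
        if self.n_drinkers < 0:
            errors.append("n_drinkers negative")
        return errors


@dataclass
class Subset:
    """A pooling subset: all estimates for one (indicator, stratum) cell."""

    label: str
    records: list[StudyRecord]
    eligible: bool

    @property
    def n_studies(self) -> int:
        return len({r.study_id for r in self.records})

    @property
    def k(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# File input / output
# ---------------------------------------------------------------------------

_MANDATORY_COLUMNS = ("study_id", "estimate_id", "indicator")

_INT_COLUMNS = ("n_total", "n_drinkers", "n_inc", "n_dec", "n_start", "n_stop")
_PROP_COLUMNS = ("prop_drinkers", "prop_women", "p_inc", "p_dec", "p_before", "p_during")
_BOOL_COLUMNS = ("weighted", "convenience_sample")
_ENUM_COLUMNS: Mapping[str, type] = {
    "sub_region": SubRegion,
    "period": Period,
    "design": Design,
    "population": Population,
    "stratum": Stratum,
    "indicator": Indicator,
    "age_profile": AgeProfile,
}


@dataclass
class Schema:
    """Column mapping and unit flags for a study table.

    ``columns`` maps record field names to file column names (identity by
    default).  When ``proportions_as_percent`` is set, all proportion columns
    are divided by 100 on read (so ``45`` or ``"45%"`` becomes ``0.45``).
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    proportions_as_percent: bool = False
    sep: str | None = None  # None: infer from extension (.tsv -> tab)

    def column(self, name: str) -> str:
        return self.columns.get(name, name)


def _parse_proportion(value, percent: bool) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "":
            return None
        if value.endswith("%"):
            return float(value[:-1]) / 100.0
        value = float(value)
    return float(value) / 100.0 if percent else float(value)


def _parse_count(value, column: str, row: int) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "":
            return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"row {row}: non-numeric count {value!r} in column {column!r}")
    if f != int(f):
        raise SchemaError(f"row {row}: count {value!r} in column {column!r} is not an integer")
    return int(f)


def _parse_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes", "y"}
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    return bool(value)


def read_studies(
    path: str | Path,
    schema: Schema | None = None,
    strict: bool = True,
) -> list[StudyRecord]:
    """Read and validate a study table (UTF-8 CSV or TSV with header row).

    Parameters
    ----------
    path
        Input file.  ``.tsv`` extension selects tab separation unless the
        schema overrides it.
    schema
        Optional column mapping and unit flags.
    strict
        When true (default), any invariant violation raises
        :class:`ValidationError` naming the offending rows.  When false,
        invalid rows are dropped and recorded in the validation report
        available through :func:`validation_report`.
    """
    schema = schema or Schema()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = schema.sep or ("\t" if path.suffix.lower() in {".tsv", ".tab"} else ",")
    df = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")

    missing = [c for c in _MANDATORY_COLUMNS if schema.column(c) not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[StudyRecord] = []
    problems: list[tuple[int, list[str]]] = []
    for i, row in enumerate(df.to_dict("records")):
        rec = _record_from_row(row, schema, row_number=i + 2)  # +2: header + 1-based
        errs = rec.validate()
        if errs:
            problems.append((i + 2, errs))
        else:
            records.append(rec)
    read_studies._last_report = {  # type: ignore[attr-defined]
        "path": str(path),
        "rows": int(len(df)),
        "valid": len(records),
        "invalid": [{"row": r, "errors": e} for r, e in problems],
    }
    if strict and problems:
        msgs = "; ".join(f"row {r}: {', '.join(e)}" for r, e in problems)
        raise ValidationError(msgs)
    return records


def validation_report() -> dict:
    """Validation report of the most recent :func:`read_studies` call."""
    return getattr(read_studies, "_last_report", {})


def _record_from_row(row: Mapping, schema: Schema, row_number: int) -> StudyRecord:
    def get(name):
        col = schema.column(name)
        return row.get(col)

    kwargs: dict = {}
    for name in ("study_id", "estimate_id", "country"):
        v = get(name)
        if v is not None and not (isinstance(v, float) and math.isnan(v)):
            kwargs[name] = str(v).strip()
    kwargs.setdefault("study_id", "")
    kwargs.setdefault("estimate_id", "")
    for name, enum_cls in _ENUM_COLUMNS.items():
        v = get(name)
        if v is not None and not (isinstance(v, float) and math.isnan(v)) and str(v).strip():
            try:
                kwargs[name] = enum_cls(str(v).strip())
            except ValueError:
                raise SchemaError(
                    f"row {row_number}: {str(v).strip()!r} is not a valid {name}"
                )
    for name in _INT_COLUMNS:
        v = _parse_count(get(name), name, row_number)
        if v is not None:
            kwargs[name] = v
    for name in _PROP_COLUMNS:
        v = _parse_proportion(get(name), schema.proportions_as_percent)
        if v is not None:
            kwargs[name] = v
    for name in _BOOL_COLUMNS:
        v = get(name)
        if v is not None:
            kwargs[name] = _parse_bool(v)
    return StudyRecord(**kwargs)


def write_studies(records: Sequence[StudyRecord], path: str | Path) -> None:
    """Write records to CSV (or TSV by extension); round-trips read_studies."""
    path = Path(path)
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d.pop("provenance")
        for k, v in list(d.items()):
            if isinstance(v, enum.Enum):
                d[k] = v.value
        rows.append(d)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, encoding="utf-8")


def write_validation_report(path: str | Path) -> None:
    Path(path).write_text(json.dumps(validation_report(), indent=2))


# ---------------------------------------------------------------------------
# Denominator reconstruction and start/stop folding
# ---------------------------------------------------------------------------


def estimate_drinker_n(record: StudyRecord) -> int:
    """Reconstruct the drinker denominator of a record.

    An explicitly given ``n_drinkers`` is returned unchanged.  Otherwise the
    denominator is the total sample size multiplied by the proportion of
    current drinkers and, for gender-stratified rows, by the proportion of
    women (or of men).  Surveys not reporting the drinker proportion fall
    back to the total sample size.  The result is stored on the record; a
    provenance flag marks reconstructed denominators.
    """
    if record.n_drinkers is not None:
        return record.n_drinkers
    if record.n_total is None:
        raise ValidationError(f"{record.estimate_id}: neither n_drinkers nor n_total present")
    n = float(record.n_total)
    if record.prop_drinkers is not None:
        n *= record.prop_drinkers
        record.provenance["n_drinkers_estimated"] = True
    if record.stratum in (Stratum.WOMEN, Stratum.MEN):
        if record.prop_women is None:
            raise ValidationError(
                f"{record.estimate_id}: stratum {record.stratum.value!r} needs prop_women "
                "when n_drinkers is not given"
            )
        share = record.prop_women if record.stratum is Stratum.WOMEN else 1.0 - record.prop_women
        n *= share
        record.provenance["n_drinkers_estimated"] = True
    record.n_drinkers = _round_half_up(n)
    return record.n_drinkers


def fold_start_stop(record: StudyRecord) -> StudyRecord:
    """Fold respondents who started/stopped drinking into the change counts.

    Starters count as increases, stoppers as decreases, and both widen the
    drinker denominator.  Returns a new record; the original counts are kept
    under ``provenance['pre_fold']``.  Records without start/stop information
    are returned unchanged.
    """
    n_start = record.n_start or 0
    n_stop = record.n_stop or 0
    if n_start == 0 and n_stop == 0:
        return record
    if record.n_drinkers is None:
        raise ValidationError(f"{record.estimate_id}: folding start/stop requires n_drinkers")
    new = dataclasses.replace(record)
    new.provenance = dict(record.provenance)
    new.provenance["pre_fold"] = {
        "n_drinkers": record.n_drinkers,
        "n_inc": record.n_inc,
        "n_dec": record.n_dec,
        "n_start": record.n_start,
        "n_stop": record.n_stop,
    }
    new.n_drinkers = record.n_drinkers + n_start + n_stop
    new.n_inc = (record.n_inc or 0) + n_start
    new.n_dec = (record.n_dec or 0) + n_stop
    new.n_start = None
    new.n_stop = None
    return new


# ---------------------------------------------------------------------------
# Monthly waves -> pandemic periods
# ---------------------------------------------------------------------------

#: month number -> period, for calendar year 2020; later years are all P3.
_DEFAULT_CALENDAR = {3: Period.P1, 4: Period.P1, 5: Period.P1, 6: Period.P1,
                     7: Period.P2, 8: Period.P2, 9: Period.P2,
                     10: Period.P3, 11: Period.P3, 12: Period.P3}


def assign_period(month: str, calendar: Mapping[int, Period] | None = None) -> Period:
    """Map an ISO ``YYYY-MM`` month to its pandemic period."""
    calendar = calendar or _DEFAULT_CALENDAR
    year_s, _, month_s = month.partition("-")
    year, mon = int(year_s), int(month_s)
    if year > 2020:
        return Period.P3
    if year < 2020 or mon < min(calendar):
        raise ValidationError(f"month {month!r} precedes the observation window")
    return calendar[mon]


def average_periods(
    waves: Sequence[MonthlyWave],
    calendar: Mapping[int, Period] | None = None,
    template: StudyRecord | None = None,
) -> list[StudyRecord]:
    """Collapse monthly waves into one record per pandemic period.

    Change proportions are averaged with equal weight across the period's
    months; counts are rebuilt as round(mean p x mean n) so downstream
    effect sizes operate on integers.  ``template`` supplies the study's
    covariates (country, design, moderators) for the emitted records.
    """
    if not waves:
        raise ValidationError("average_periods requires at least one wave")
    for w in waves:
        errs = w.validate()
        if errs:
            raise ValidationError(f"wave {w.study_id}/{w.month}: {', '.join(errs)}")
    by_period: dict[Period, list[MonthlyWave]] = {}
    for w in waves:
        by_period.setdefault(assign_period(w.month, calendar), []).append(w)
    out: list[StudyRecord] = []
    for period in Period:
        group = by_period.get(period)
        if not group:
            continue
        n_mean = sum(w.n_drinkers for w in group) / len(group)
        p_inc = sum(w.p_inc for w in group) / len(group)
        p_dec = sum(w.p_dec for w in group) / len(group)
        base = dataclasses.replace(template) if template is not None else StudyRecord(
            study_id=group[0].study_id, estimate_id=""
        )
        base.study_id = group[0].study_id
        base.estimate_id = f"{group[0].study_id}:{period.value}"
        base.period = period
        base.n_drinkers = _round_half_up(n_mean)
        base.p_inc, base.p_dec = p_inc, p_dec
        base.n_inc = _round_half_up(p_inc * base.n_drinkers)
        base.n_dec = _round_half_up(p_dec * base.n_drinkers)
        base.provenance = {"averaged_months": [w.month for w in group]}
        out.append(base)
    return out


# ---------------------------------------------------------------------------
# Subset construction
# ---------------------------------------------------------------------------


def prepare_records(records: Iterable[StudyRecord]) -> list[StudyRecord]:
    """Run the full preparation chain on validated records.

    Reconstructs missing drinker denominators, rebuilds counts from reported
    proportions where only proportions are given, and folds start/stop
    respondents.  Returns new/updated records ready for effect-size
    computation.
    """
    out = []
    for rec in records:
        if rec.n_total is not None or rec.n_drinkers is not None:
            estimate_drinker_n(rec)
        if rec.n_drinkers is not None:
            if rec.n_inc is None and rec.p_inc is not None:
                rec.n_inc = _round_half_up(rec.p_inc * rec.n_drinkers)
                rec.provenance["counts_reconstructed"] = True
            if rec.n_dec is None and rec.p_dec is not None:
                rec.n_dec = _round_half_up(rec.p_dec * rec.n_drinkers)
                rec.provenance["counts_reconstructed"] = True
        out.append(fold_start_stop(rec))
    return out


def _subset_label(indicator: Indicator, stratum: Stratum) -> str:
    if indicator is Indicator.OVERALL_USE:
        return f"overall/{stratum.value}"
    return indicator.value.lower()


def build_subsets(records: Sequence[StudyRecord]) -> list[Subset]:
    """Group general-population records into the pooling subsets.

    Subsets are one per (indicator, stratum) cell: overall use split into
    total/women/men, plus frequency, quantity, heavy episodic drinking and
    prevalence (total stratum).  For the total-sample analysis a study's
    total row is preferred; studies reporting only gender-stratified rows
    contribute both gender rows as separate estimates.  A subset is eligible
    for pooling only when it draws on at least five independent studies; a
    study with several estimate rows counts once.
    """
    general = [r for r in records if r.population is Population.GENERAL]
    subsets: list[Subset] = []
    for indicator in Indicator:
        pool = [r for r in general if r.indicator is indicator]
        # total-sample subset: total rows, else gender rows of that study
        with_total = {r.study_id for r in pool if r.stratum is Stratum.TOTAL}
        total_records = [
            r for r in pool
            if r.stratum is Stratum.TOTAL or r.study_id not in with_total
        ]
        label = _subset_label(indicator, Stratum.TOTAL)
        n_studies = len({r.study_id for r in total_records})
        subsets.append(Subset(label, total_records, n_studies >= MIN_INDEPENDENT_STUDIES))
        if indicator is Indicator.OVERALL_USE:
            for stratum in (Stratum.WOMEN, Stratum.MEN):
                strat_records = [r for r in pool if r.stratum is stratum]
                n_studies = len({r.study_id for r in strat_records})
                subsets.append(
                    Subset(
                        _subset_label(indicator, stratum),
                        strat_records,
                        n_studies >= MIN_INDEPENDENT_STUDIES,
                    )
                )
    return subsets
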