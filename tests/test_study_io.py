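import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from drinkmeta import study_io
from drinkmeta.study_io import (
    AgeProfile,
    Indicator,
    MonthlyWave,
    Period,
    Schema,
    Stratum,
    StudyRecord,
    SubRegion,
    ValidationError,
    SchemaError,
    assign_period,
    average_periods,
    build_subsets,
    estimate_drinker_n,
    fold_start_stop,
    read_studies,
    write_studies,
)


def rec(**kw):
    kw.setdefault("study_id", "S1")
    kw.setdefault("estimate_id", "S1:e1")
    return StudyRecord(**kw)


class TestReadWrite:
    def test_round_trip_preserves_all_fields(self, tmp_path):
        records = [
            rec(country="DE", sub_region=SubRegion.WESTERN, period=Period.P2,
                n_total=1000, prop_drinkers=0.8, prop_women=0.52, weighted=True,
                n_drinkers=800, n_inc=100, n_dec=150),
            rec(study_id="S2", estimate_id="S2:e1", indicator=Indicator.PREVALENCE,
                n_total=400, p_before=0.7, p_during=0.6,
                age_profile=AgeProfile.YOUNGER, convenience_sample=True),
            rec(study_id="S3", estimate_id="S3:e1", stratum=Stratum.WOMEN,
                n_drinkers=250, n_inc=20, n_dec=30, n_start=3, n_stop=5),
        ]
        path = tmp_path / "t.csv"
        write_studies(records, path)
        back = read_studies(path)
        assert len(back) == 3
        for orig, rt in zip(records, back):
            for f in dataclasses.fields(StudyRecord):
                if f.name == "provenance":
                    continue
                assert getattr(rt, f.name) == getattr(orig, f.name), f.name

    def test_negative_count_rejected_with_row_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "study_id,estimate_id,indicator,n_drinkers,n_inc,n_dec\n"
            "S1,e1,overall_use,100,-2,5\n"
        )
        with pytest.raises(ValidationError, match="row 2"):
            read_studies(path)

    def test_percent_flag_normalises_proportions(self, tmp_path):
        path = tmp_path / "pct.csv"
        path.write_text(
            "study_id,estimate_id,indicator,n_total,prop_drinkers\n"
            "S1,e1,overall_use,1000,45%\nS2,e2,overall_use,1000,45\n"
        )
        records = read_studies(path, Schema(proportions_as_percent=True))
        assert records[0].prop_drinkers == pytest.approx(0.45)
        assert records[1].prop_drinkers == pytest.approx(0.45)

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("study_id,n_total\nS1,100\n")
        with pytest.raises(SchemaError, match="estimate_id"):
            read_studies(path)

    def test_inconsistent_counts_rejected(self, tmp_path):
        path = tmp_path / "inc.csv"
        path.write_text(
            "study_id,estimate_id,indicator,n_drinkers,n_inc,n_dec\n"
            "S1,e1,overall_use,100,60,50\n"
        )
        with pytest.raises(ValidationError, match="exceeds"):
            read_studies(path)


class TestDrinkerDenominator:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(n_total=1000, prop_drinkers=0.8), 800),
            (dict(n_total=1000), 1000),  # fallback: total sample size
            (dict(n_total=1000, prop_drinkers=0.8, prop_women=0.5,
                  stratum=Stratum.WOMEN), 400),
            (dict(n_total=1000, prop_drinkers=0.8, prop_women=0.4,
                  stratum=Stratum.MEN), 480),
            (dict(n_total=999, prop_drinkers=0.5), 500),  # round half up
            (dict(n_total=123, n_drinkers=77), 77),  # explicit wins
        ],
    )
    def test_examples(self, kwargs, expected):
        assert estimate_drinker_n(rec(**kwargs)) == expected

    def test_stratified_without_gender_share_fails(self):
        with pytest.raises(ValidationError, match="prop_women"):
            estimate_drinker_n(rec(n_total=1000, stratum=Stratum.WOMEN))

    @given(
        n_total=st.integers(1, 10**6),
        delta=st.integers(0, 1000),
        p=st.floats(0.0, 1.0),
        dp=st.floats(0.0, 0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_n_total_and_proportion(self, n_total, delta, p, dp):
        base = estimate_drinker_n(rec(n_total=n_total, prop_drinkers=p))
        bigger_n = estimate_drinker_n(rec(n_total=n_total + delta, prop_drinkers=p))
        bigger_p = estimate_drinker_n(
            rec(n_total=n_total, prop_drinkers=min(1.0, p + dp))
        )
        assert bigger_n >= base
        assert bigger_p >= base


class TestFoldStartStop:
    def test_both_sides_folded(self):
        r = rec(n_drinkers=100, n_inc=10, n_dec=20, n_start=5, n_stop=10)
        out = fold_start_stop(r)
        assert (out.n_drinkers, out.n_inc, out.n_dec) == (115, 15, 30)
        assert out.provenance["pre_fold"]["n_inc"] == 10

    def test_zero_start_stop_is_identity(self):
        r = rec(n_drinkers=100, n_inc=10, n_dec=20, n_start=0, n_stop=0)
        assert fold_start_stop(r) is r

    def test_one_sided_fold(self):
        r = rec(n_drinkers=100, n_inc=10, n_dec=20, n_stop=8)
        out = fold_start_stop(r)
        assert (out.n_drinkers, out.n_inc, out.n_dec) == (108, 10, 28)

    def test_fold_without_denominator_fails(self):
        with pytest.raises(ValidationError, match="n_drinkers"):
            fold_start_stop(rec(n_inc=1, n_dec=2, n_start=3))

    @given(
        n=st.integers(10, 10000),
        inc=st.integers(0, 5),
        dec=st.integers(0, 5),
        start=st.integers(0, 100),
        stop=st.integers(0, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_fold_conserves_original_counts(self, n, inc, dec, start, stop):
        out = fold_start_stop(
            rec(n_drinkers=n, n_inc=inc, n_dec=dec, n_start=start, n_stop=stop)
        )
        assert out.n_inc - start == inc
        assert out.n_dec - stop == dec
        assert out.n_drinkers - start - stop == n


class TestAveragePeriods:
    def test_mean_of_two_months_within_period(self):
        waves = [
            MonthlyWave("S1", "2020-03", 1000, 0.2, 0.3),
            MonthlyWave("S1", "2020-04", 1000, 0.3, 0.3),
        ]
        out = average_periods(waves)
        assert len(out) == 1
        assert out[0].period is Period.P1
        assert out[0].n_inc == 250  # mean p_inc 0.25 x 1000

    def test_single_wave_identity(self):
        out = average_periods([MonthlyWave("S1", "2020-11", 500, 0.1, 0.2)])
        assert len(out) == 1
        assert out[0].period is Period.P3
        assert (out[0].n_inc, out[0].n_dec) == (50, 100)

    def test_waves_spanning_period_boundary_split(self):
        waves = [
            MonthlyWave("S1", "2020-06", 1000, 0.2, 0.2),
            MonthlyWave("S1", "2020-07", 1000, 0.4, 0.2),
        ]
        out = average_periods(waves)
        assert [r.period for r in out] == [Period.P1, Period.P2]
        assert out[0].n_inc == 200 and out[1].n_inc == 400

    def test_empty_wave_list_rejected(self):
        with pytest.raises(ValidationError):
            average_periods([])

    def test_2021_months_are_late_period(self):
        assert assign_period("2021-02") is Period.P3


class TestBuildSubsets:
    def test_fewer_than_five_studies_ineligible(self):
        records = [
            rec(study_id=f"S{i}", estimate_id=f"S{i}:e",
                indicator=Indicator.FREQUENCY, n_drinkers=100, n_inc=10, n_dec=10)
            for i in range(4)
        ]
        subsets = {s.label: s for s in build_subsets(records)}
        assert not subsets["frequency"].eligible
        assert subsets["frequency"].n_studies == 4

    def test_gender_rows_substitute_missing_total_rows(self):
        records = []
        for i in range(4):  # four studies with a total row
            records.append(rec(study_id=f"S{i}", estimate_id=f"S{i}:t",
                               n_drinkers=100, n_inc=10, n_dec=10))
        for i in range(4, 6):  # two studies with gender rows only
            for stratum in (Stratum.WOMEN, Stratum.MEN):
                records.append(rec(study_id=f"S{i}",
                                   estimate_id=f"S{i}:{stratum.value}",
                                   stratum=stratum, n_drinkers=50,
                                   n_inc=5, n_dec=5, prop_women=0.5))
        subsets = {s.label: s for s in build_subsets(records)}
        total = subsets["overall/total"]
        assert total.k == 8
        assert total.n_studies == 6
        assert total.eligible

    def test_total_row_preferred_over_gender_rows(self):
        records = [
            rec(study_id="S1", estimate_id="S1:t", n_drinkers=100, n_inc=1, n_dec=1),
            rec(study_id="S1", estimate_id="S1:w", stratum=Stratum.WOMEN,
                n_drinkers=50, n_inc=1, n_dec=1),
        ]
        subsets = {s.label: s for s in build_subsets(records)}
        assert [r.estimate_id for r in subsets["overall/total"].records] == ["S1:t"]
        assert [r.estimate_id for r in subsets["overall/women"].records] == ["S1:w"]

    def test_empty_input_gives_ineligible_subsets(self):
        subsets = build_subsets([])
        assert subsets and all(not s.eligible for s in subsets)

    def test_partition_every_record_in_exactly_one_indicator_cell(
        self, synthetic_records
    ):
        subsets = build_subsets(synthetic_records)
        seen = [r.estimate_id for s in subsets for r in s.records]
        assert sorted(seen) == sorted(r.estimate_id for r in synthetic_records)
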