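"""Cohort selection, index-time rules, windows, aggregators and encodings."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinsynth.errors import ConfigError, SamplingError, SchemaError
from clinsynth.query import (
    CohortQuery,
    Predicate,
    abnormal_flags,
    aggregate_feature,
    derive_composite,
    nonsepsis_index_time,
    one_hot_encode,
    sample_controls,
    select_cohort,
    window_slice,
)


def _long(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "event_type", "timestamp", "attr_name", "attr_value"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


@pytest.fixture
def toy_events():
    rows = []
    for pid in ["p1", "p2", "p3", "p4", "p5"]:
        rows.append([pid, "admission", "2015-01-01", "ward", "icu"])
    rows.append(["p2", "diagnosis", "2015-02-01", "code", "A41"])
    rows.append(["p4", "diagnosis", "2015-03-01", "code", "A41"])
    rows.append(["p5", "diagnosis", "2015-03-01", "code", "J18"])
    return _long(rows)


class TestSelectCohort:
    def test_empty_filter_list_returns_everyone(self, toy_events):
        assert select_cohort(toy_events, CohortQuery()) == {"p1", "p2", "p3", "p4", "p5"}

    def test_diagnosis_code_filter_matches_brute_force(self, toy_events):
        query = CohortQuery(filters=[Predicate("code", "==", "A41", event_type="diagnosis")])
        # independent oracle: scan every record
        expected = {
            r.patient_id
            for r in toy_events.itertuples()
            if r.event_type == "diagnosis" and r.attr_name == "code" and r.attr_value == "A41"
        }
        assert select_cohort(toy_events, query) == expected == {"p2", "p4"}

    def test_compound_filter_on_constructed_cohort(self):
        # 8 patients with sex/vital-status demographics and a dated cancer
        # diagnosis carrying age at the event
        rows = []
        profile = {
            "p1": ("male", "deceased", "2012-05-01", 45),
            "p2": ("male", "deceased", "2009-05-01", 45),  # diagnosed too early
            "p3": ("male", "deceased", "2013-05-01", 55),  # too old at diagnosis
            "p4": ("male", "alive", "2014-05-01", 40),     # not deceased
            "p5": ("female", "deceased", "2015-05-01", 44),  # wrong sex
            "p6": ("male", "deceased", "2016-05-01", 49),
            "p7": ("male", "deceased", "2010-01-01", 30),  # boundary date excluded (>)
            "p8": ("female", "alive", "2011-05-01", 60),
        }
        for pid, (sex, status, date, age) in profile.items():
            rows.append([pid, "demographic", "2000-01-01", "sex", sex])
            rows.append([pid, "demographic", "2020-01-01", "vital_status", status])
            rows.append([pid, "diagnosis", date, "code", "C61"])
            rows.append([pid, "diagnosis", date, "age_at_event", str(age)])
        events = _long(rows)
        query = CohortQuery(
            filters=[
                Predicate("sex", "==", "male"),
                Predicate("vital_status", "==", "deceased"),
                Predicate("timestamp", ">", "2010-01-01", event_type="diagnosis"),
                Predicate("age_at_event", "<", 50, event_type="diagnosis"),
            ]
        )
        # oracle: independent per-patient predicate evaluation
        expected = {
            pid
            for pid, (sex, status, date, age) in profile.items()
            if sex == "male" and status == "deceased"
            and pd.Timestamp(date) > pd.Timestamp("2010-01-01") and age < 50
        }
        assert select_cohort(events, query) == expected == {"p1", "p6"}

    def test_unknown_attribute_raises_schema_error(self, toy_events):
        with pytest.raises(SchemaError):
            select_cohort(toy_events, CohortQuery(filters=[Predicate("nope", "==", 1)]))

    def test_order_insensitive(self, toy_events):
        query = CohortQuery(filters=[Predicate("code", "==", "A41", event_type="diagnosis")])
        shuffled = toy_events.sample(frac=1.0, random_state=3)
        assert select_cohort(toy_events, query) == select_cohort(shuffled, query)


class TestIndexTime:
    @pytest.mark.parametrize(
        "hours,expected_offset",
        [(48, 24), (20, 12), (24, 12)],  # midpoint, short stay, boundary
    )
    def test_index_rules(self, hours, expected_offset):
        admit = pd.Timestamp("2016-01-01 00:00")
        got = nonsepsis_index_time(admit, admit + pd.Timedelta(hours=hours))
        assert got == admit + pd.Timedelta(hours=expected_offset)

    def test_reversed_interval_errors(self):
        t = pd.Timestamp("2016-01-01")
        with pytest.raises(ConfigError):
            nonsepsis_index_time(t, t - pd.Timedelta(hours=1))


class TestWindowSlice:
    def _events_at_leads(self, leads_h):
        index = pd.Timestamp("2016-06-01 12:00")
        rows = [
            ["p1", "lab", index - pd.Timedelta(hours=h), "lactate", "2.0"] for h in leads_h
        ]
        return _long(rows), index

    def test_closed_window_boundaries(self):
        events, index = self._events_at_leads([10, 2, 6, 24, 25])
        kept = window_slice(events, index, (6, 24))
        leads = (index - kept["timestamp"]).dt.total_seconds() / 3600
        assert sorted(leads) == [6, 10, 24]

    def test_zero_to_inf_keeps_all_past_events(self):
        events, index = self._events_at_leads([0, 5, 1000, -3])
        kept = window_slice(events, index, (0, float("inf")))
        assert len(kept) == 3  # the future event (-3 h lead) is dropped


class TestAggregate:
    @pytest.mark.parametrize(
        "values,agg,expected",
        [
            ([], "count", 0.0),
            ([1, 2, 3], "median", 2.0),
            ([1, 2, 3, 4], "variance", 5.0 / 3.0),  # n-1 denominator, by hand
            ([1, 2, 3], "sum", 6.0),
            ([4, 1, 9], "first", 4.0),
            ([4, 1, 9], "last", 9.0),
        ],
    )
    def test_aggregators(self, values, agg, expected):
        assert aggregate_feature(values, agg) == pytest.approx(expected, abs=1e-12)

    def test_empty_non_count_is_missing(self):
        assert math.isnan(aggregate_feature([], "median"))

    def test_unknown_aggregator(self):
        with pytest.raises(ConfigError):
            aggregate_feature([1], "mode")

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.lists(st.floats(-1e6, 1e6), max_size=20),
        b=st.lists(st.floats(-1e6, 1e6), max_size=20),
    )
    def test_sum_additive_over_concatenation(self, a, b):
        if not a and not b:  # empty-sum convention: missing, not 0
            assert math.isnan(aggregate_feature([], "sum"))
            return
        whole = aggregate_feature(a + b, "sum")
        parts = (0.0 if not a else aggregate_feature(a, "sum")) + (
            0.0 if not b else aggregate_feature(b, "sum")
        )
        assert whole == pytest.approx(parts, rel=1e-9, abs=1e-6)


class TestComposite:
    def test_bmi(self):
        assert derive_composite({"weight": 80, "height": 1.6}, "weight / height ** 2") == pytest.approx(31.25)

    def test_shock_index(self):
        assert derive_composite({"hr": 100, "sbp": 125}, "hr / sbp") == pytest.approx(0.8)

    def test_missing_operand_propagates(self, caplog):
        with caplog.at_level("INFO", logger="clinsynth.query"):
            got = derive_composite({"weight": 80, "height": float("nan")}, "weight / height ** 2")
        assert math.isnan(got)
        assert len(caplog.records) == 1

    def test_only_arithmetic_allowed(self):
        with pytest.raises(ConfigError):
            derive_composite({"x": 1}, "__import__('os')")


class TestOneHot:
    def test_four_level_race_gives_four_columns(self):
        col = pd.Series(["white", "black", "unknown", "other", "white"], name="race")
        enc = one_hot_encode(col)
        assert enc.shape[1] == 4
        assert (enc.sum(axis=1) == 1).all()  # partition of unity

    def test_two_level_stays_single_column(self):
        col = pd.Series(["female", "male", "female"], name="sex")
        enc = one_hot_encode(col)
        assert list(enc.columns) == ["sex_male"]
        assert enc["sex_male"].tolist() == [0, 1, 0]

    def test_unseen_level_is_schema_error(self):
        col = pd.Series(["a", "b", "z"], name="c")
        with pytest.raises(SchemaError):
            one_hot_encode(col, levels=["a", "b", "c"])


class TestAbnormalFlags:
    def test_below_threshold_not_flagged(self):
        assert abnormal_flags(1.0, high=2.0) == {"high": 0}

    def test_critical_implies_high(self):
        flags = abnormal_flags(4.5, high=2.0, critical=4.0)
        assert flags == {"critical": 1, "high": 1}

    def test_value_at_threshold_is_flagged(self):
        assert abnormal_flags(2.0, high=2.0)["high"] == 1

    def test_unordered_thresholds_error(self):
        with pytest.raises(ConfigError):
            abnormal_flags(1.0, low=3.0, high=2.0)


class TestSampleControls:
    def test_exact_ratio_and_disjointness(self):
        cases = [f"c{i}" for i in range(643)]
        pool = [f"x{i}" for i in range(3000)] + cases
        controls = sample_controls(cases, pool, ratio=2, seed=11)
        assert len(controls) == 1286
        assert len(set(controls)) == 1286
        assert set(controls).isdisjoint(cases)

    def test_pool_exhausted(self):
        with pytest.raises(SamplingError):
            sample_controls(list("abcdef"), list("abcdefghij"), ratio=2, seed=0)

    def test_seed_reproducibility(self):
        pool = [f"x{i}" for i in range(50)]
        assert sample_controls(["c"], pool, 3, seed=5) == sample_controls(["c"], pool, 3, seed=5)
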