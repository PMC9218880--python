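import datetime as dt

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pharmacohort.cohort import (apply_eligibility, classify_user_type,
                                 resolve_index_date)
from conftest import make_dispensings, make_patients


class TestResolveIndexDate:
    def test_last_dispensing_before_registration(self):
        # registration 2016-05-31 with no same-day dispensing: the last
        # dispensing before it (2016-05-30) becomes the index date
        idx = resolve_index_date(dt.date(2016, 5, 31), [dt.date(2016, 5, 30)])
        assert idx == dt.date(2016, 5, 30)

    def test_same_day_dispensing_wins(self):
        idx = resolve_index_date(
            dt.date(2016, 5, 31),
            [dt.date(2016, 5, 31), dt.date(2016, 5, 1)])
        assert idx == dt.date(2016, 5, 31)

    def test_only_later_dispensings_give_no_index(self):
        assert resolve_index_date(dt.date(2016, 5, 31),
                                  [dt.date(2016, 6, 10)]) is None

    def test_missing_registration_gives_no_index(self):
        assert resolve_index_date(None, [dt.date(2016, 5, 30)]) is None

    @given(reg_offset=st.integers(0, 2000),
           disp_offsets=st.lists(st.integers(0, 2000), min_size=1,
                                 max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_never_after_registration(self, reg_offset, disp_offsets):
        base = dt.date(2015, 1, 1)
        reg = base + dt.timedelta(days=reg_offset)
        dates = [base + dt.timedelta(days=o) for o in disp_offsets]
        idx = resolve_index_date(reg, dates)
        if idx is not None:
            assert idx <= reg
            assert idx == max(d for d in dates if d <= reg)


def _toy_population():
    """Six patients engineered so exactly two survive all five filters."""
    patients = make_patients([
        # survivor, intervention arm
        ("S1", 1960, "female", "asthma", "sara", "2017-06-01"),
        # survivor, control arm
        ("S2", 1955, "male", "copd", "not_interested", "2017-06-01"),
        # under 18 at first dispensing
        ("X1", 2005, "male", "asthma", "sara", "2017-06-01"),
        # participation status never registered
        ("X2", 1960, "female", "asthma", None, "2017-06-01"),
        # registration 40 days after the last prior R03 dispensing
        ("X3", 1960, "female", "asthma", "sara", "2017-07-11"),
        # indication outside asthma/COPD
        ("X4", 1960, "male", "bronchitis", "sara", "2017-06-01"),
    ])
    rows = []
    for pid in ("S1", "S2", "X1", "X2", "X3", "X4"):
        rows += [
            (pid, "2015-06-01", "R03BA01", 30),   # predates the 2-year window
            (pid, "2017-06-01", "R03BA01", 30),   # anchor dispensing
            (pid, "2018-08-01", "N02BE01", 10),   # postdates the window
        ]
    # X3's only R03 on/before its registration (2017-07-11) is 2017-06-01:
    # gap = 40 days -> criterion 3
    return patients, make_dispensings(rows)


class TestEligibility:
    def test_toy_population_partition(self):
        patients, dispensings = _toy_population()
        cohort, trace = apply_eligibility(patients, dispensings)
        assert set(cohort["patient_id"]) == {"S1", "S2"}
        assert trace.n_input == 6 and trace.n_final == 2
        assert sum(trace.counts.values()) + trace.n_final == trace.n_input
        assert trace.counts["criterion_1_age_under_18"] == 1
        assert trace.counts["criterion_2_status_missing"] == 1
        assert trace.counts["criterion_3_registration_gap"] == 1
        assert trace.counts["criterion_4_indication"] == 1

    def test_group_mapping(self):
        patients, dispensings = _toy_population()
        cohort, _ = apply_eligibility(patients, dispensings)
        groups = dict(zip(cohort["patient_id"], cohort["group"]))
        assert groups == {"S1": "sara", "S2": "control"}

    def test_thirty_day_boundary_is_inclusive(self):
        patients = make_patients([
            ("B1", 1960, "female", "asthma", "sara", "2017-07-01"),  # 30 days
            ("B2", 1960, "female", "asthma", "sara", "2017-07-02"),  # 31 days
        ])
        rows = []
        for pid in ("B1", "B2"):
            rows += [(pid, "2015-06-01", "R03BA01", 30),
                     (pid, "2017-06-01", "R03BA01", 30),
                     (pid, "2018-08-01", "N02BE01", 10)]
        cohort, trace = apply_eligibility(patients, make_dispensings(rows))
        assert set(cohort["patient_id"]) == {"B1"}
        assert trace.counts["criterion_3_registration_gap"] == 1

    def test_data_completeness_requires_strict_bracketing(self):
        patients = make_patients([
            ("C1", 1960, "female", "asthma", "sara", "2017-06-01"),
        ])
        # records exactly on the window bounds do not satisfy criterion 5
        dispensings = make_dispensings([
            ("C1", "2016-06-01", "R03BA01", 30),   # = before_window.start
            ("C1", "2017-06-01", "R03BA01", 30),
            ("C1", "2018-05-31", "N02BE01", 10),   # = after_window.end
        ])
        cohort, trace = apply_eligibility(patients, dispensings)
        assert len(cohort) == 0
        assert trace.counts["criterion_5_data_completeness"] == 1

    def test_window_arithmetic_fixed_365_days_across_leap_years(self):
        patients, dispensings = _toy_population()
        cohort, _ = apply_eligibility(patients, dispensings)
        for _, row in cohort.iterrows():
            assert (row["before_end"] - row["before_start"]).days + 1 == 365
            assert (row["after_end"] - row["after_start"]).days + 1 == 365
            assert (row["after_start"] - row["before_end"]).days == 1
            assert row["after_start"] == row["index_date"]

    @given(offset=st.integers(0, 1460))
    @settings(max_examples=120, deadline=None)
    def test_window_invariants_hold_for_any_index_date(self, offset):
        reg = pd.Timestamp("2016-01-01") + pd.Timedelta(days=offset)
        patients = make_patients([
            ("P1", 1960, "female", "asthma", "sara", str(reg.date())),
        ])
        dispensings = make_dispensings([
            ("P1", str((reg - pd.Timedelta(days=900)).date()), "R03BA01", 30),
            ("P1", str(reg.date()), "R03BA01", 30),
            ("P1", str((reg + pd.Timedelta(days=400)).date()), "N02BE01", 1),
        ])
        cohort, _ = apply_eligibility(patients, dispensings)
        assert len(cohort) == 1
        row = cohort.iloc[0]
        assert (row["before_end"] - row["before_start"]).days + 1 == 365
        assert (row["after_end"] - row["after_start"]).days + 1 == 365


class TestUserType:
    def _cohort_for(self, dispensings):
        patients = make_patients([
            ("P1", 1960, "female", "asthma", "sara", "2017-06-01"),
        ])
        cohort, _ = apply_eligibility(patients, dispensings)
        assert len(cohort) == 1
        return cohort

    def test_no_before_window_r03_is_new(self):
        cohort = self._cohort_for(make_dispensings([
            ("P1", "2015-01-01", "N02BE01", 10),
            ("P1", "2017-06-01", "R03BA01", 30),
            ("P1", "2017-08-01", "R03BA01", 30),
            ("P1", "2017-10-01", "R03BA01", 30),
            ("P1", "2018-08-01", "N02BE01", 10),
        ]))
        disp = make_dispensings([
            ("P1", "2015-01-01", "N02BE01", 10),
            ("P1", "2017-06-01", "R03BA01", 30),
            ("P1", "2017-08-01", "R03BA01", 30),
            ("P1", "2017-10-01", "R03BA01", 30),
            ("P1", "2018-08-01", "N02BE01", 10),
        ])
        typed = classify_user_type(cohort, disp)
        assert typed["user_type"].iloc[0] == "new"

    def test_single_before_window_r03_is_chronic(self):
        disp = make_dispensings([
            ("P1", "2015-01-01", "R03BA01", 30),
            ("P1", "2017-01-15", "R03BA01", 30),   # inside before-window
            ("P1", "2017-06-01", "R03BA01", 30),
            ("P1", "2018-08-01", "N02BE01", 10),
        ])
        typed = classify_user_type(self._cohort_for(disp), disp)
        assert typed["user_type"].iloc[0] == "chronic"

    def test_index_date_dispensing_belongs_to_after_window(self):
        # the index-day dispensing is the patient's only R03: new user
        disp = make_dispensings([
            ("P1", "2015-01-01", "N02BE01", 10),
            ("P1", "2017-06-01", "R03BA01", 30),
            ("P1", "2018-08-01", "N02BE01", 10),
        ])
        typed = classify_user_type(self._cohort_for(disp), disp)
        assert typed["user_type"].iloc[0] == "new"

    def test_reliever_r03_counts_by_default_but_not_with_maintenance_set(
            self, code_sets):
        disp = make_dispensings([
            ("P1", "2015-01-01", "N02BE01", 10),
            ("P1", "2017-01-15", "R03AC02", 0),    # reliever in before-window
            ("P1", "2017-06-01", "R03BA01", 30),
            ("P1", "2018-08-01", "N02BE01", 10),
        ])
        cohort = self._cohort_for(disp)
        assert classify_user_type(cohort, disp)["user_type"].iloc[0] == \
            "chronic"
        restricted = classify_user_type(
            cohort, disp, maintenance_set=code_sets.r03_maintenance)
        assert restricted["user_type"].iloc[0] == "new"
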