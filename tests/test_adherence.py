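import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pharmacohort.adherence import (adherence_outcomes, compute_pdc,
                                    coverage_intervals, summarize_adherence)
from pharmacohort.datamodel import DateWindow
from conftest import (concat_cohort, day_set_pdc, make_cohort_entry,
                      make_dispensings)


class TestCoverageIntervals:
    def test_fifteen_day_supply_spans_to_june_third(self):
        [(start, end)] = coverage_intervals([dt.date(2015, 5, 20)], [15])
        assert start == dt.date(2015, 5, 20)
        assert end == dt.date(2015, 6, 3)

    def test_april_supply_spans_to_april_29(self):
        [(start, end)] = coverage_intervals([dt.date(2017, 4, 15)], [15])
        assert end == dt.date(2017, 4, 29)

    def test_single_day_supply(self):
        [(start, end)] = coverage_intervals([dt.date(2016, 1, 1)], [1])
        assert start == end == dt.date(2016, 1, 1)

    def test_zero_covering_days_skipped(self):
        assert coverage_intervals([dt.date(2016, 1, 1)], [0]) == []


class TestComputePdc:
    def test_leading_days_from_pre_window_dispensing(self):
        # window starts 2015-05-30; the last prior dispensing (May 20 x15)
        # covers May 30..June 3 (5 days); June 4..17 is not covered until
        # the next dispensing on June 18
        window = DateWindow(dt.date(2015, 5, 30), dt.date(2016, 5, 28))
        profile = compute_pdc(
            "F1", window,
            [dt.date(2015, 5, 20), dt.date(2015, 6, 18)], [15, 15])
        assert not profile.missing
        # 5 days from the boundary record + 15 from the in-window record
        assert profile.days_covered == 20
        oracle = day_set_pdc(window.start,
                             [dt.date(2015, 5, 20), dt.date(2015, 6, 18)],
                             [15, 15])
        assert profile.pdc == pytest.approx(oracle, abs=1e-9)

    def test_tail_truncated_at_window_end(self):
        # window ends 2017-05-30; last dispensing April 15 x15 covers
        # through April 29; April 30..May 30 (31 days) is not covered
        window = DateWindow(dt.date(2016, 5, 31), dt.date(2017, 5, 30))
        dates = [dt.date(2016, 5, 31) + dt.timedelta(days=30 * k)
                 for k in range(11)] + [dt.date(2017, 4, 15)]
        covers = [30] * 11 + [15]
        profile = compute_pdc("F2", window, dates, covers)
        uncovered = 365 - profile.days_covered
        assert uncovered == 31
        assert profile.pdc == pytest.approx(
            day_set_pdc(window.start, dates, covers), abs=1e-9)

    def test_full_year_supply_gives_100(self):
        window = DateWindow(dt.date(2016, 1, 1), dt.date(2016, 12, 30))
        profile = compute_pdc("P1", window, [dt.date(2016, 1, 1)], [365])
        assert profile.pdc == 100.0

    def test_overlapping_supplies_do_not_stack(self):
        # two 100-day supplies overlapping by 20 days: union is 180 days
        window = DateWindow(dt.date(2016, 1, 1), dt.date(2016, 12, 30))
        profile = compute_pdc(
            "P1", window,
            [dt.date(2016, 1, 1), dt.date(2016, 3, 21)], [100, 100])
        assert profile.days_covered == 180
        assert profile.pdc == pytest.approx(100.0 * 180 / 365, abs=0.005)
        assert round(profile.pdc, 2) == 49.32

    def test_no_record_on_or_before_window_end_is_missing(self):
        window = DateWindow(dt.date(2016, 1, 1), dt.date(2016, 12, 30))
        profile = compute_pdc("P1", window, [dt.date(2017, 6, 1)], [30])
        assert profile.missing

    def test_stale_early_record_gives_zero_not_missing(self):
        window = DateWindow(dt.date(2016, 1, 1), dt.date(2016, 12, 30))
        profile = compute_pdc("P1", window, [dt.date(2014, 1, 1)], [30])
        assert not profile.missing and profile.pdc == 0.0

    @given(st.lists(st.tuples(st.integers(-420, 420), st.integers(1, 120)),
                    min_size=1, max_size=10))
    @settings(max_examples=300, deadline=None)
    def test_interval_union_matches_day_scan(self, records):
        window = DateWindow(dt.date(2016, 1, 1), dt.date(2016, 12, 30))
        dates = [window.start + dt.timedelta(days=o) for o, _ in records]
        covers = [c for _, c in records]
        profile = compute_pdc("P1", window, dates, covers)
        if not profile.missing:
            assert profile.pdc == pytest.approx(
                day_set_pdc(window.start, dates, covers), abs=1e-9)

    @given(st.lists(st.tuples(st.integers(-420, 420), st.integers(1, 120)),
                    min_size=2, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_adding_a_record_never_decreases_coverage(self, records):
        window = DateWindow(dt.date(2016, 1, 1), dt.date(2016, 12, 30))
        dates = [window.start + dt.timedelta(days=o) for o, _ in records]
        covers = [c for _, c in records]
        full = compute_pdc("P1", window, dates, covers)
        reduced = compute_pdc("P1", window, dates[:-1], covers[:-1])
        if not reduced.missing:
            assert full.days_covered >= reduced.days_covered
        assert 0 <= full.days_covered <= 365


class TestAdherenceOutcomes:
    def _chronic_disp(self, pid="P1"):
        # 30-day refills every 30 days: perfect coverage in both windows
        dates = pd.date_range("2016-05-01", "2018-07-01", freq="30D")
        return make_dispensings(
            [(pid, str(d.date()), "R03BA02", 30) for d in dates])

    def test_min_dispensing_rule_excludes_sparse_users(self):
        cohort = concat_cohort(
            make_cohort_entry("P1", "2017-06-01"),
            make_cohort_entry("P2", "2017-06-01"),
        )
        disp = pd.concat([
            self._chronic_disp("P1"),
            make_dispensings([
                ("P2", "2016-08-01", "R03BA02", 30),
                ("P2", "2017-08-01", "R03BA02", 30),
            ]),
        ], ignore_index=True)
        out = adherence_outcomes(cohort, disp)
        assert set(out["patient_id"]) == {"P1"}
        assert out.attrs["n_excluded_min_dispensings"] == 1

    def test_identical_refill_pattern_gives_zero_difference(self):
        cohort = make_cohort_entry("P1", "2017-06-01")
        out = adherence_outcomes(cohort, self._chronic_disp())
        row = out.iloc[0]
        assert row["pdc_before"] == 100.0 and row["pdc_after"] == 100.0
        assert row["difference"] == 0.0
        assert bool(row["adherent_before"]) and bool(row["adherent_after"])

    def test_new_user_gets_after_window_only(self):
        cohort = make_cohort_entry("P1", "2017-06-01", user_type="new")
        dates = pd.date_range("2017-06-01", "2018-07-01", freq="30D")
        disp = make_dispensings(
            [("P1", str(d.date()), "R03BA02", 30) for d in dates])
        out = adherence_outcomes(cohort, disp)
        row = out.iloc[0]
        assert np.isnan(row["pdc_before"]) and np.isnan(row["difference"])
        assert row["pdc_after"] == 100.0

    def test_nebulizer_rows_excluded_from_coverage(self):
        cohort = make_cohort_entry("P1", "2017-06-01")
        disp = pd.concat([
            self._chronic_disp("P1"),
            make_dispensings([
                ("P1", "2017-07-15", "R03AL04", 300, np.nan, "nebulizer"),
            ]),
        ], ignore_index=True)
        with_neb = adherence_outcomes(cohort, disp)
        without = adherence_outcomes(cohort, self._chronic_disp("P1"))
        assert with_neb.iloc[0]["pdc_after"] == without.iloc[0]["pdc_after"]

    def test_hand_computed_fixture_patient(self):
        # before-window [2016-06-01, 2017-05-31]: refills 90 days apart
        # with 60-day supplies -> 2/3 coverage once the chain starts
        cohort = make_cohort_entry("P1", "2017-06-01")
        rows = [("P1", "2016-03-04", "R03BA02", 60)]
        for k in range(9):
            day = pd.Timestamp("2016-06-02") + pd.Timedelta(days=90 * k)
            rows.append(("P1", str(day.date()), "R03BA02", 60))
        disp = make_dispensings(rows)
        out = adherence_outcomes(cohort, disp)
        dates = [pd.Timestamp(r[1]).date() for r in rows]
        covers = [r[3] for r in rows]
        expected_before = day_set_pdc(dt.date(2016, 6, 1), dates, covers)
        expected_after = day_set_pdc(dt.date(2017, 6, 1), dates, covers)
        assert out.iloc[0]["pdc_before"] == pytest.approx(expected_before,
                                                          abs=0.005)
        assert out.iloc[0]["pdc_after"] == pytest.approx(expected_after,
                                                         abs=0.005)

    def test_summary_reports_days_covered_scale(self):
        cohort = make_cohort_entry("P1", "2017-06-01", group="control")
        summary = summarize_adherence(
            adherence_outcomes(cohort, self._chronic_disp()))
        after = summary.query("group == 'control' and period == 'after'")
        assert after["pdc_mean"].iloc[0] == 100.0
        assert after["days_covered_mean"].iloc[0] == 365.0
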