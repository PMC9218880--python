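"""Proportion of days covered (PDC) with the "at least one" method.

A patient's adherence to the maintenance R03 class over one 365-day
analysis window is the percentage of window days on which at least one
maintenance medication was available. Each dispensing covers the closed
interval [dispense_date, dispense_date + covering_days - 1]; availability
is the union of those intervals — overlapping supplies are not appended
end-to-end (no stockpiling), and a day counts if any one product covers
it (concurrent adherence to the class).

Boundary handling: records dated before the window contribute their
in-window residual days, and the last in-window record's coverage is
truncated at the window end — both fall out of intersecting closed
intervals with the window. When a patient has no record dated on or
before the window end, coverage is undeterminable and the PDC is missing.

PDCs are on the 0-100 scale with a fixed denominator of 365 days; the
good-adherence cutoff of 0.8 is applied as PDC >= 80.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import AtcCodeSets, DateWindow

logger = logging.getLogger(__name__)

WINDOW_DAYS = 365
ADHERENCE_CUTOFF = 80.0
MIN_DISPENSINGS = 3


def coverage_intervals(dates, covering_days) -> list[tuple[dt.date, dt.date]]:
    """Closed coverage interval per record; zero covering days -> skipped."""
    out = []
    for d, c in zip(dates, covering_days):
        if c <= 0:
            logger.warning("dispensing on %s with covering_days=0: empty "
                           "interval", d)
            continue
        out.append((d, d + dt.timedelta(days=int(c) - 1)))
    return out


def _union_length(starts: np.ndarray, ends: np.ndarray, w0: int, w1: int) -> int:
    """Days in [w0, w1] covered by the union of closed intervals (int days)."""
    s = np.maximum(starts, w0)
    e = np.minimum(ends, w1)
    keep = e >= s
    if not keep.any():
        return 0
    s, e = s[keep], e[keep]
    order = np.argsort(s, kind="stable")
    s, e = s[order], e[order]
    total = 0
    cur_s, cur_e = int(s[0]), int(e[0])
    for i in range(1, len(s)):
        si, ei = int(s[i]), int(e[i])
        if si > cur_e + 1:
            total += cur_e - cur_s + 1
            cur_s, cur_e = si, ei
        else:
            cur_e = max(cur_e, ei)
    total += cur_e - cur_s + 1
    return total


@dataclass(frozen=True)
class CoverageProfile:
    """PDC result for one patient-window."""

    patient_id: str
    window: DateWindow
    days_covered: int
    missing: bool

    @property
    def pdc(self) -> float:
        return 100.0 * self.days_covered / WINDOW_DAYS


def compute_pdc(patient_id: str, window: DateWindow, dates, covering_days
                ) -> CoverageProfile:
    """PDC for one window from all of a patient's maintenance records.

    ``dates``/``covering_days`` should include records outside the window:
    earlier records determine coverage of the window's leading days.
    """
    day_nums = np.array([(d - dt.date(1970, 1, 1)).days for d in dates],
                        dtype=np.int64)
    covers = np.asarray(list(covering_days), dtype=np.int64)
    keep = covers > 0
    day_nums, covers = day_nums[keep], covers[keep]
    w0 = (window.start - dt.date(1970, 1, 1)).days
    w1 = (window.end - dt.date(1970, 1, 1)).days
    if not (day_nums <= w1).any():
        return CoverageProfile(patient_id, window, 0, missing=True)
    covered = _union_length(day_nums, day_nums + covers - 1, w0, w1)
    return CoverageProfile(patient_id, window, covered, missing=False)


def _maintenance_records(dispensings: pd.DataFrame, sets: AtcCodeSets
                         ) -> pd.DataFrame:
    disp = dispensings.copy()
    disp["dispense_date"] = pd.to_datetime(disp["dispense_date"])
    maint = disp.loc[disp["atc_code"].isin(sets.r03_maintenance)]
    if "product_form" in maint.columns:
        neb = maint["product_form"].isin(sets.nebulizer_forms)
        if neb.any():
            logger.info("excluding %d nebulizer-form record(s) from the "
                        "adherence analysis", int(neb.sum()))
        maint = maint.loc[~neb.fillna(False)]
    else:
        logger.warning("no product_form column: nebulizer exclusion is a "
                       "no-op")
    return maint


def adherence_outcomes(cohort: pd.DataFrame, dispensings: pd.DataFrame,
                       sets: AtcCodeSets | None = None,
                       min_dispensings: int = MIN_DISPENSINGS,
                       cutoff: float = ADHERENCE_CUTOFF) -> pd.DataFrame:
    """Per-patient adherence outcomes for a cohort with resolved user types.

    Patients with fewer than ``min_dispensings`` maintenance records inside
    the 2-year analysis period are excluded (early cessation / fully
    nonadherent). Chronic users get (pdc_before, pdc_after, difference);
    new users only pdc_after. Undeterminable coverage yields NaN PDCs.
    """
    if sets is None:
        sets = AtcCodeSets()
    maint = _maintenance_records(dispensings, sets)

    merged = maint[["patient_id", "dispense_date", "covering_days"]].merge(
        cohort[["patient_id", "before_start", "after_end"]], on="patient_id")
    in_period = (merged["dispense_date"] >= merged["before_start"]) & \
                (merged["dispense_date"] <= merged["after_end"])
    n_in_period = merged.loc[in_period].groupby("patient_id").size()

    cohort_typed = cohort.loc[cohort["user_type"].isin(["new", "chronic"])]
    counts = cohort_typed["patient_id"].map(n_in_period).fillna(0)
    eligible = cohort_typed.loc[counts >= min_dispensings].copy()
    n_excluded = len(cohort_typed) - len(eligible)
    if n_excluded:
        logger.info("adherence: excluded %d patient(s) with < %d maintenance "
                    "dispensings in the 2-year period", n_excluded,
                    min_dispensings)

    # int day representation for speed
    day0 = np.int64(0)
    maint_days = maint["dispense_date"].values.astype("datetime64[D]").astype(np.int64)
    maint_cov = maint["covering_days"].to_numpy(np.int64)
    maint_pid = maint["patient_id"].to_numpy()
    order = np.argsort(maint_pid, kind="stable")
    maint_pid, maint_days, maint_cov = (maint_pid[order], maint_days[order],
                                        maint_cov[order])
    uniq, idx_start = np.unique(maint_pid, return_index=True)
    slices = {pid: (int(s), int(e)) for pid, s, e in
              zip(uniq, idx_start, np.append(idx_start[1:], len(maint_pid)))}

    b0 = eligible["before_start"].values.astype("datetime64[D]").astype(np.int64)
    a0 = eligible["after_start"].values.astype("datetime64[D]").astype(np.int64)
    pids = eligible["patient_id"].to_numpy()
    types = eligible["user_type"].to_numpy()
    pdc_before = np.full(len(eligible), np.nan)
    pdc_after = np.full(len(eligible), np.nan)
    for i in range(len(eligible)):
        s, e = slices.get(pids[i], (0, 0))
        days, covs = maint_days[s:e], maint_cov[s:e]
        keep = covs > 0
        days, covs = days[keep], covs[keep]
        ends = days + covs - 1

        def window_pdc(w0: int) -> float:
            w1 = w0 + WINDOW_DAYS - 1
            if not (days <= w1).any():
                return np.nan
            return 100.0 * _union_length(days, ends, w0, w1) / WINDOW_DAYS

        pdc_after[i] = window_pdc(int(a0[i]))
        if types[i] == "chronic":
            pdc_before[i] = window_pdc(int(b0[i]))

    out = eligible[["patient_id", "group", "indication", "gender",
                    "age_at_first_dispensing", "user_type"]].copy()
    out["pdc_before"] = pdc_before
    out["pdc_after"] = pdc_after
    out["difference"] = pdc_after - pdc_before
    out["adherent_before"] = pd.array(pdc_before >= cutoff, dtype="boolean")
    out["adherent_before"] = out["adherent_before"].mask(np.isnan(pdc_before))
    out["adherent_after"] = pd.array(pdc_after >= cutoff, dtype="boolean")
    out["adherent_after"] = out["adherent_after"].mask(np.isnan(pdc_after))
    out = out.reset_index(drop=True)
    out.attrs["n_excluded_min_dispensings"] = n_excluded
    return out


def summarize_adherence(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Chronic-user group-by-period summary: PDC and days covered, mean (SD)."""
    chronic = outcomes.loc[outcomes["user_type"] == "chronic"].dropna(
        subset=["pdc_before", "pdc_after"])
    n_total = len(chronic)
    rows = []
    for group in ("control", "sara"):
        sub = chronic.loc[chronic["group"] == group]
        n = len(sub)
        pct = round(100.0 * n / n_total, 2) if n_total else np.nan
        for period, col in (("before", "pdc_before"), ("after", "pdc_after")):
            days = sub[col] * WINDOW_DAYS / 100.0
            rows.append({
                "group": group, "period": period,
                "pdc_mean": round(sub[col].mean(), 2),
                "pdc_sd": round(sub[col].std(ddof=1), 2),
                "days_covered_mean": round(days.mean(), 2),
                "days_covered_sd": round(days.std(ddof=1), 2),
                "difference_score": (round(sub["difference"].mean(), 2)
                                     if period == "after" else np.nan),
                "n": n, "pct": pct})
    return pd.DataFrame(rows)
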