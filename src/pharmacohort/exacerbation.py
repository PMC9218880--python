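"""Exacerbation proxy: short-course oral prednis(ol)one dispensings.

A dispensing of prednisolone (H02AB06) or prednisone (H02AB07) counts as
one exacerbation when it reflects a daily dosage of exactly 30 or 40 mg
for 5 to 14 covering days — the short burst regimen recommended by Dutch
general-practice guidelines for asthma/COPD exacerbations. Each
qualifying record is one event; courses are not merged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import AtcCodeSets

logger = logging.getLogger(__name__)

QUALIFYING_DOSES_MG = frozenset({30, 40})
MIN_COURSE_DAYS = 5
MAX_COURSE_DAYS = 14


def is_exacerbation_course(atc_code: str, daily_dose_mg: float | None,
                           covering_days: int,
                           sets: AtcCodeSets | None = None,
                           dose_set: frozenset = QUALIFYING_DOSES_MG,
                           min_days: int = MIN_COURSE_DAYS,
                           max_days: int = MAX_COURSE_DAYS) -> bool:
    """True iff the record is a qualifying short prednis(ol)one course."""
    if sets is None:
        sets = AtcCodeSets()
    if atc_code not in sets.prednisone:
        return False
    if daily_dose_mg is None or pd.isna(daily_dose_mg):
        logger.warning("prednisone record without daily_dose_mg; not counted")
        return False
    return daily_dose_mg in dose_set and min_days <= covering_days <= max_days


def qualifying_mask(dispensings: pd.DataFrame,
                    sets: AtcCodeSets | None = None,
                    dose_set: frozenset = QUALIFYING_DOSES_MG,
                    min_days: int = MIN_COURSE_DAYS,
                    max_days: int = MAX_COURSE_DAYS) -> pd.Series:
    """Vectorized :func:`is_exacerbation_course` over a dispensing frame."""
    if sets is None:
        sets = AtcCodeSets()
    pred = dispensings["atc_code"].isin(sets.prednisone)
    n_missing = int((pred & dispensings["daily_dose_mg"].isna()).sum())
    if n_missing:
        logger.warning("%d prednisone record(s) without daily_dose_mg; "
                       "not counted", n_missing)
    dose_ok = dispensings["daily_dose_mg"].isin(list(dose_set))
    days_ok = dispensings["covering_days"].between(min_days, max_days)
    return pred & dose_ok & days_ok


def count_exacerbations(cohort: pd.DataFrame, dispensings: pd.DataFrame,
                        sets: AtcCodeSets | None = None) -> pd.DataFrame:
    """Per-patient exacerbation counts in each window and their difference.

    A qualifying course dated on the index date counts in the after-window
    (the index date starts the after-window). Every cohort member appears
    in the output, with zero counts when no qualifying course exists.
    """
    disp = dispensings.copy()
    disp["dispense_date"] = pd.to_datetime(disp["dispense_date"])
    qual = disp.loc[qualifying_mask(disp, sets),
                    ["patient_id", "dispense_date"]]
    merged = qual.merge(
        cohort[["patient_id", "before_start", "before_end",
                "after_start", "after_end"]], on="patient_id")
    in_before = (merged["dispense_date"] >= merged["before_start"]) & \
                (merged["dispense_date"] <= merged["before_end"])
    in_after = (merged["dispense_date"] >= merged["after_start"]) & \
               (merged["dispense_date"] <= merged["after_end"])
    before = merged.loc[in_before].groupby("patient_id").size()
    after = merged.loc[in_after].groupby("patient_id").size()

    out = cohort[["patient_id", "group", "indication", "gender",
                  "age_at_first_dispensing"]].copy()
    out["count_before"] = out["patient_id"].map(before).fillna(0).astype(int)
    out["count_after"] = out["patient_id"].map(after).fillna(0).astype(int)
    out["difference"] = out["count_after"] - out["count_before"]
    return out


def summarize_exacerbations(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Group-by-period summary: mean (SD) rates, difference score, n (%)."""
    n_total = len(outcomes)
    rows = []
    for group in ("control", "sara"):
        sub = outcomes.loc[outcomes["group"] == group]
        n = len(sub)
        pct = round(100.0 * n / n_total, 2) if n_total else np.nan
        rows.append({
            "group": group, "period": "before",
            "mean": round(sub["count_before"].mean(), 2),
            "sd": round(sub["count_before"].std(ddof=1), 2),
            "difference_score": np.nan, "n": n, "pct": pct})
        rows.append({
            "group": group, "period": "after",
            "mean": round(sub["count_after"].mean(), 2),
            "sd": round(sub["count_after"].std(ddof=1), 2),
            "difference_score": round(sub["difference"].mean(), 2),
            "n": n, "pct": pct})
    return pd.DataFrame(rows)
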