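"""Antimycotic co-treatment in the ICS-using subpopulation.

Inhaled corticosteroids can cause oral candidiasis; its prevalence is
proxied by dispensings of oral/topical antimycotics. Patients enter this
analysis when they have at least one ICS dispensing anywhere in the 2-year
analysis period (so group denominators are constant across periods); per
window the outcome is binary — 1 if any antimycotic was dispensed in that
window, else 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import AtcCodeSets

logger = logging.getLogger(__name__)


def antimycotic_outcomes(cohort: pd.DataFrame, dispensings: pd.DataFrame,
                         sets: AtcCodeSets | None = None) -> pd.DataFrame:
    """Per-patient binary antimycotic outcomes among ICS users."""
    if sets is None:
        sets = AtcCodeSets()
    disp = dispensings.copy()
    disp["dispense_date"] = pd.to_datetime(disp["dispense_date"])

    windows = cohort[["patient_id", "group", "before_start", "before_end",
                      "after_start", "after_end"]]

    def window_flags(codes: frozenset) -> pd.DataFrame:
        sub = disp.loc[disp["atc_code"].isin(codes),
                       ["patient_id", "dispense_date"]].merge(
            windows, on="patient_id")
        in_before = (sub["dispense_date"] >= sub["before_start"]) & \
                    (sub["dispense_date"] <= sub["before_end"])
        in_after = (sub["dispense_date"] >= sub["after_start"]) & \
                   (sub["dispense_date"] <= sub["after_end"])
        return pd.DataFrame({
            "before": in_before.groupby(sub["patient_id"]).any(),
            "after": in_after.groupby(sub["patient_id"]).any(),
        })

    ics = window_flags(sets.ics)
    anti = window_flags(sets.antimycotics)

    out = cohort[["patient_id", "group", "indication", "gender",
                  "age_at_first_dispensing"]].copy()
    def lookup(ids: pd.Series, flags: pd.DataFrame, period: str) -> pd.Series:
        mapped = ids.map(flags[period]).astype("boolean")
        return mapped.fillna(False).astype(bool)

    out["ics_user_before"] = lookup(out["patient_id"], ics, "before")
    out["ics_user_after"] = lookup(out["patient_id"], ics, "after")
    out = out.loc[out["ics_user_before"] | out["ics_user_after"]].copy()
    out["antimycotic_before"] = lookup(out["patient_id"], anti,
                                       "before").astype(int)
    out["antimycotic_after"] = lookup(out["patient_id"], anti,
                                      "after").astype(int)
    return out.reset_index(drop=True)


def antimycotic_prevalence(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Group-by-period counts and percentages of antimycotic dispensing.

    Percentage = 100 x (patients with outcome 1) / (group size), to two
    decimals; an empty group yields NaN with a logged diagnostic.
    """
    n_total = len(outcomes)
    rows = []
    for group in ("control", "sara"):
        sub = outcomes.loc[outcomes["group"] == group]
        n = len(sub)
        if n == 0:
            logger.warning("antimycotic prevalence: empty group %r", group)
        for period in ("before", "after"):
            count = int(sub[f"antimycotic_{period}"].sum()) if n else 0
            rows.append({
                "group": group, "period": period,
                "n_antimycotic": count,
                "pct_antimycotic": round(100.0 * count / n, 2) if n else np.nan,
                "n_group": n,
                "pct_group": (round(100.0 * n / n_total, 2)
                              if n_total else np.nan)})
    return pd.DataFrame(rows)
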