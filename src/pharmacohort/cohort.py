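"""Index-date resolution, analysis windows, eligibility filters, user types.

Each patient's timeline is split at the index date into two fixed 365-day
analysis windows: ``before`` = [index-365, index-1] and ``after`` =
[index, index+364] (closed intervals, so window lengths are uniform across
leap years). The index date is the registration date when an R03
dispensing occurred that day, otherwise the last R03 dispensing date before
registration — equivalently, the latest R03 dispensing on or before the
registration date.

Five eligibility criteria are applied in order, each exclusion attributed
to the first failing criterion:

1. age >= 18 years at the first available dispensing record;
2. participation status registered (intervention or control);
3. registration at most 30 days after the index date (longer delays make
   the before/after split unreliable);
4. disease indication asthma or COPD;
5. at least one dispensing record (of any medication) strictly before the
   2-year analysis period and at least one strictly after, ensuring
   complete dispensing data over the period.

Patients whose index date cannot be resolved (no R03 dispensing on or
before registration) are traced separately between criteria 2 and 3.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import pandas as pd

MAX_REGISTRATION_GAP_DAYS = 30
WINDOW_DAYS = 365

#: trace keys in application order
FILTER_STEPS = (
    "no_dispensings",
    "criterion_1_age_under_18",
    "criterion_2_status_missing",
    "no_index_date",
    "criterion_3_registration_gap",
    "criterion_4_indication",
    "criterion_5_data_completeness",
)

COHORT_COLUMNS = [
    "patient_id", "group", "index_date", "before_start", "before_end",
    "after_start", "after_end", "age_at_first_dispensing", "gender",
    "indication", "user_type",
]


@dataclass
class FilterTrace:
    """Per-criterion exclusion counts; partitions the input patients."""

    n_input: int
    counts: dict = field(default_factory=dict)
    n_final: int = 0

    def check(self) -> None:
        assert self.n_input == self.n_final + sum(self.counts.values()), \
            "filter trace does not partition the input"

    def to_frame(self) -> pd.DataFrame:
        rows = [{"step": "input", "n": self.n_input, "excluded": 0}]
        remaining = self.n_input
        for step in FILTER_STEPS:
            excluded = self.counts.get(step, 0)
            remaining -= excluded
            rows.append({"step": step, "n": remaining, "excluded": excluded})
        rows.append({"step": "final_cohort", "n": self.n_final, "excluded": 0})
        return pd.DataFrame(rows)


def resolve_index_date(registration_date: dt.date | None,
                       r03_dates) -> dt.date | None:
    """Latest R03 dispensing date on or before registration, or None.

    Covers both definition branches: if a dispensing falls exactly on the
    registration date that date is returned; otherwise the last dispensing
    before it. Returns None when registration is missing or no dispensing
    is available on/before it.
    """
    if registration_date is None or pd.isna(registration_date):
        return None
    eligible = [d for d in r03_dates if d <= registration_date]
    return max(eligible) if eligible else None


def _r03_mask(dispensings: pd.DataFrame) -> pd.Series:
    return dispensings["atc_code"].str.startswith("R03")


def apply_eligibility(patients: pd.DataFrame, dispensings: pd.DataFrame,
                      max_registration_gap: int = MAX_REGISTRATION_GAP_DAYS,
                      ) -> tuple[pd.DataFrame, FilterTrace]:
    """Apply the five eligibility criteria; return (cohort, trace).

    The cohort frame has one row per surviving patient with the resolved
    index date, both window bounds, and demographics; ``user_type`` is
    left as "n/a" (see :func:`classify_user_type`).
    """
    trace = FilterTrace(n_input=len(patients))
    frame = patients.copy()
    frame["registration_date"] = pd.to_datetime(frame["registration_date"])
    disp = dispensings.copy()
    disp["dispense_date"] = pd.to_datetime(disp["dispense_date"])

    per_patient = disp.groupby("patient_id")["dispense_date"].agg(["min", "max"])
    per_patient.columns = ["first_any", "last_any"]
    frame = frame.merge(per_patient, left_on="patient_id", right_index=True,
                        how="left")

    def drop(mask: pd.Series, step: str) -> None:
        nonlocal frame
        trace.counts[step] = int(mask.sum())
        frame = frame.loc[~mask]

    drop(frame["first_any"].isna(), "no_dispensings")

    frame["age_at_first_dispensing"] = (
        frame["first_any"].dt.year - frame["birth_year"])
    drop(frame["age_at_first_dispensing"] < 18, "criterion_1_age_under_18")

    drop(frame["status"].isna(), "criterion_2_status_missing")

    # index date: latest R03 dispensing on/before registration
    r03 = disp.loc[_r03_mask(disp), ["patient_id", "dispense_date"]]
    r03 = r03.merge(frame[["patient_id", "registration_date"]], on="patient_id")
    r03 = r03.loc[r03["dispense_date"] <= r03["registration_date"]]
    index_dates = r03.groupby("patient_id")["dispense_date"].max()
    frame = frame.merge(index_dates.rename("index_date"),
                        left_on="patient_id", right_index=True, how="left")
    drop(frame["registration_date"].isna() | frame["index_date"].isna(),
         "no_index_date")

    gap = (frame["registration_date"] - frame["index_date"]).dt.days
    drop(gap > max_registration_gap, "criterion_3_registration_gap")

    drop(~frame["indication"].isin(["asthma", "copd"]), "criterion_4_indication")

    frame["before_start"] = frame["index_date"] - pd.Timedelta(days=WINDOW_DAYS)
    frame["before_end"] = frame["index_date"] - pd.Timedelta(days=1)
    frame["after_start"] = frame["index_date"]
    frame["after_end"] = frame["index_date"] + pd.Timedelta(days=WINDOW_DAYS - 1)
    complete = (frame["first_any"] < frame["before_start"]) & \
               (frame["last_any"] > frame["after_end"])
    drop(~complete, "criterion_5_data_completeness")

    frame["group"] = frame["status"].map(
        {"sara": "sara", "not_interested": "control",
         "not_now_or_not_offered": "control"})
    frame["user_type"] = "n/a"
    trace.n_final = len(frame)
    trace.check()
    cohort = frame[COHORT_COLUMNS].reset_index(drop=True)
    return cohort, trace


def classify_user_type(cohort: pd.DataFrame, dispensings: pd.DataFrame,
                       maintenance_set: frozenset | None = None,
                       ) -> pd.DataFrame:
    """Label each cohort member "new" or "chronic".

    New users have zero R03 dispensings dated within the before-window
    (the index date itself belongs to the after-window); chronic users have
    at least one. By default any R03 dispensing counts; pass a
    ``maintenance_set`` of ATC codes to restrict the rule to maintenance
    products.
    """
    disp = dispensings.copy()
    disp["dispense_date"] = pd.to_datetime(disp["dispense_date"])
    if maintenance_set is None:
        relevant = disp.loc[_r03_mask(disp)]
    else:
        relevant = disp.loc[disp["atc_code"].isin(maintenance_set)]
    merged = relevant[["patient_id", "dispense_date"]].merge(
        cohort[["patient_id", "before_start", "before_end"]], on="patient_id")
    in_before = merged.loc[
        (merged["dispense_date"] >= merged["before_start"])
        & (merged["dispense_date"] <= merged["before_end"])]
    chronic_ids = set(in_before["patient_id"].unique())
    out = cohort.copy()
    out["user_type"] = [
        "chronic" if pid in chronic_ids else "new"
        for pid in out["patient_id"]
    ]
    return out
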