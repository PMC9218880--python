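import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pharmacohort.datamodel import AtcCodeSets

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def code_sets() -> AtcCodeSets:
    return AtcCodeSets()


def make_dispensings(rows) -> pd.DataFrame:
    """Build a dispensing frame from (pid, date, atc, covering[, dose[, form]])."""
    out = []
    for row in rows:
        pid, date, atc, covering = row[:4]
        dose = row[4] if len(row) > 4 else np.nan
        form = row[5] if len(row) > 5 else None
        out.append({
            "patient_id": pid,
            "dispense_date": pd.Timestamp(date),
            "atc_code": atc,
            "amount": float(covering),
            "covering_days": int(covering),
            "daily_dose_mg": dose,
            "product_form": form,
        })
    frame = pd.DataFrame(out)
    frame["product_form"] = frame["product_form"].astype("string")
    return frame


def make_patients(rows) -> pd.DataFrame:
    """Build a patient frame from (pid, birth_year, gender, indication,
    status, registration_date)."""
    out = []
    for pid, birth_year, gender, indication, status, reg in rows:
        out.append({
            "patient_id": pid,
            "birth_year": birth_year,
            "gender": gender,
            "indication": indication,
            "pharmacy_id": "PH001",
            "status": status,
            "registration_date": (pd.Timestamp(reg) if reg else pd.NaT),
        })
    frame = pd.DataFrame(out)
    frame["status"] = frame["status"].astype("string")
    return frame


def make_cohort_entry(pid: str, index_date: str, group: str = "sara",
                      user_type: str = "chronic", indication: str = "asthma",
                      gender: str = "female", age: int = 50) -> pd.DataFrame:
    idx = pd.Timestamp(index_date)
    return pd.DataFrame([{
        "patient_id": pid, "group": group, "index_date": idx,
        "before_start": idx - pd.Timedelta(days=365),
        "before_end": idx - pd.Timedelta(days=1),
        "after_start": idx, "after_end": idx + pd.Timedelta(days=364),
        "age_at_first_dispensing": age, "gender": gender,
        "indication": indication, "user_type": user_type,
    }])


def concat_cohort(*entries) -> pd.DataFrame:
    return pd.concat(entries, ignore_index=True)


@pytest.fixture
def figure_patient_dispensings() -> pd.DataFrame:
    """The worked refill history: dispensing 2015-05-20 x15 days, next
    refill 2015-06-18, around a before-window starting 2015-05-30."""
    return make_dispensings([
        ("F1", "2015-05-20", "R03BA02", 15),
        ("F1", "2015-06-18", "R03BA02", 15),
    ])


def day_set_pdc(window_start: dt.date, dates, covering_days) -> float:
    """Brute-force day-enumeration PDC oracle (0-100): scan each of the 365
    window days and test membership in any closed coverage interval."""
    covered = 0
    for offset in range(365):
        day = window_start + dt.timedelta(days=offset)
        for d, c in zip(dates, covering_days):
            if c > 0 and d <= day <= d + dt.timedelta(days=int(c) - 1):
                covered += 1
                break
    return 100.0 * covered / 365.0
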