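"""Readers and writers for the two input tables and result tables.

Dates are ISO-8601 (YYYY-MM-DD) everywhere. Readers validate row by row:
rows violating an invariant (unparseable date, negative covering days,
malformed ATC code) are dropped and reported in ``frame.attrs["diagnostics"]``
as human-readable strings citing the 1-based data row number, and logged.
A missing required column raises :class:`ConfigurationError`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .datamodel import ATC_PATTERN, GENDERS, INDICATIONS, STATUSES

logger = logging.getLogger(__name__)

DISPENSING_COLUMNS = [
    "patient_id", "dispense_date", "atc_code", "amount", "covering_days",
    "daily_dose_mg",
]
PATIENT_COLUMNS = [
    "patient_id", "birth_year", "gender", "indication", "pharmacy_id",
    "status", "registration_date",
]


class ConfigurationError(ValueError):
    """The input file does not match the documented table layout."""


def _apply_dialect(frame: pd.DataFrame, dialect: dict | None) -> pd.DataFrame:
    """Rename columns per the optional {source_name: canonical_name} map."""
    if dialect:
        frame = frame.rename(columns=dict(dialect))
    return frame


def _require_columns(frame: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required column(s) {missing}")


def read_dispensings(path: str | Path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a dispensing-record CSV into a validated DataFrame.

    Returns a frame with one row per accepted dispensing, ``dispense_date``
    as datetime64, and rejection diagnostics under ``attrs['diagnostics']``.
    """
    raw = pd.read_csv(path, dtype={"patient_id": str, "atc_code": str})
    raw = _apply_dialect(raw, dialect)
    if raw.empty and raw.columns.size == 0:
        logger.warning("%s: empty dispensing file", path)
        out = pd.DataFrame(columns=DISPENSING_COLUMNS)
        out.attrs["diagnostics"] = []
        return out
    _require_columns(raw, DISPENSING_COLUMNS, path)

    diagnostics: list[str] = []
    dates = pd.to_datetime(raw["dispense_date"], format="%Y-%m-%d", errors="coerce")
    covering = pd.to_numeric(raw["covering_days"], errors="coerce")
    amount = pd.to_numeric(raw["amount"], errors="coerce")
    atc_ok = raw["atc_code"].astype(str).str.match(ATC_PATTERN)

    bad_date = dates.isna()
    bad_cover = covering.isna() | (covering < 0)
    bad_amount = amount.isna() | (amount < 0)
    bad_atc = ~atc_ok
    for idx in raw.index[bad_date]:
        diagnostics.append(f"row {idx + 1}: unparseable dispense_date "
                           f"{raw.at[idx, 'dispense_date']!r}")
    for idx in raw.index[bad_cover & ~bad_date]:
        diagnostics.append(f"row {idx + 1}: invalid covering_days "
                           f"{raw.at[idx, 'covering_days']!r}")
    for idx in raw.index[bad_amount & ~bad_date & ~bad_cover]:
        diagnostics.append(f"row {idx + 1}: invalid amount {raw.at[idx, 'amount']!r}")
    for idx in raw.index[bad_atc & ~bad_date & ~bad_cover & ~bad_amount]:
        diagnostics.append(f"row {idx + 1}: malformed atc_code "
                           f"{raw.at[idx, 'atc_code']!r}")

    keep = ~(bad_date | bad_cover | bad_amount | bad_atc)
    out = raw.loc[keep].copy()
    out["dispense_date"] = dates[keep]
    out["covering_days"] = covering[keep].astype(int)
    out["amount"] = amount[keep]
    out["daily_dose_mg"] = pd.to_numeric(out["daily_dose_mg"], errors="coerce")
    if "product_form" not in out.columns:
        out["product_form"] = pd.NA
    out = out.reset_index(drop=True)
    if diagnostics:
        logger.warning("%s: rejected %d row(s); first: %s",
                       path, len(diagnostics), diagnostics[0])
    if out.empty:
        logger.warning("%s: no valid dispensing rows", path)
    out.attrs["diagnostics"] = diagnostics
    return out


def read_patients(path: str | Path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a patient-record CSV into a validated DataFrame."""
    raw = pd.read_csv(
        path, dtype={"patient_id": str, "pharmacy_id": str}, keep_default_na=False,
        na_values=[""],
    )
    raw = _apply_dialect(raw, dialect)
    _require_columns(raw, PATIENT_COLUMNS, path)

    diagnostics: list[str] = []
    birth = pd.to_numeric(raw["birth_year"], errors="coerce")
    reg = pd.to_datetime(raw["registration_date"], format="%Y-%m-%d", errors="coerce")
    gender = raw["gender"].astype(str).str.lower()
    indication = raw["indication"].astype(str).str.lower()
    status = raw["status"].astype(str).str.lower()

    bad_birth = birth.isna()
    bad_gender = ~gender.isin(GENDERS)
    bad_ind = ~indication.isin(INDICATIONS)
    # an unknown status string means SARA participation is not registered;
    # keep the row (criterion 2 excludes it downstream) but normalize to NA
    status = status.where(status.isin(STATUSES))
    # sara / not_interested require a registration date
    bad_reg = status.isin(["sara", "not_interested"]) & reg.isna() & \
        raw["registration_date"].notna()
    missing_reg = status.isin(["sara", "not_interested"]) & reg.isna()

    for idx in raw.index[bad_birth]:
        diagnostics.append(f"row {idx + 1}: invalid birth_year "
                           f"{raw.at[idx, 'birth_year']!r}")
    for idx in raw.index[bad_gender & ~bad_birth]:
        diagnostics.append(f"row {idx + 1}: unknown gender "
                           f"{raw.at[idx, 'gender']!r}")
    for idx in raw.index[bad_ind & ~bad_birth & ~bad_gender]:
        diagnostics.append(f"row {idx + 1}: unknown indication "
                           f"{raw.at[idx, 'indication']!r}")
    for idx in raw.index[missing_reg & ~bad_birth & ~bad_gender & ~bad_ind]:
        diagnostics.append(
            f"row {idx + 1}: status {status[idx]!r} without registration_date")

    keep = ~(bad_birth | bad_gender | bad_ind | missing_reg)
    out = raw.loc[keep].copy()
    out["birth_year"] = birth[keep].astype(int)
    out["gender"] = gender[keep]
    out["indication"] = indication[keep]
    out["status"] = status[keep]
    out["registration_date"] = reg[keep]
    out = out.reset_index(drop=True)
    if diagnostics:
        logger.warning("%s: rejected %d patient row(s); first: %s",
                       path, len(diagnostics), diagnostics[0])
    out.attrs["diagnostics"] = diagnostics
    return out


def write_dispensings(frame: pd.DataFrame, path: str | Path) -> None:
    """Write dispensings with ISO dates; round-trips through read_dispensings."""
    out = frame.copy()
    out["dispense_date"] = pd.to_datetime(out["dispense_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_patients(frame: pd.DataFrame, path: str | Path) -> None:
    out = frame.copy()
    reg = pd.to_datetime(out["registration_date"])
    out["registration_date"] = reg.dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a result table (generic CSV, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
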