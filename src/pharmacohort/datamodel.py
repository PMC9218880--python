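"""Domain types and ATC code sets for the dispensing-data analysis.

The analysis operates on two flat tables: pharmacy dispensing records
(one row per dispensing event) and patient records (one row per patient).
Drug classes are identified by exact 7-character WHO ATC codes; the code
sets below define the maintenance inhalation medications (R03 class) used
for adherence, the inhaled corticosteroids (ICS) subset, the systemic
prednis(ol)one codes used as the exacerbation proxy, and the oral/topical
antimycotics used as the candidiasis proxy.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field

#: WHO ATC syntax: one letter, two digits, two letters, two digits.
ATC_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

#: The 21 maintenance R03 codes (ICS, LABA, LAMA and fixed-dose combinations)
#: over which concurrent adherence is measured.
R03_MAINTENANCE: frozenset[str] = frozenset({
    "R03BA01", "R03BA02", "R03BA05", "R03BA08",
    "R03AK06", "R03AK07", "R03AK08", "R03AK10", "R03AK11",
    "R03AL03", "R03AL04", "R03AL05", "R03AL08", "R03AL09",
    "R03AC18", "R03AC13", "R03AC12",
    "R03BB04", "R03BB05", "R03BB06", "R03BB07",
})

#: Inhaled corticosteroids (single-agent); subset of the maintenance set.
ICS_CODES: frozenset[str] = frozenset({"R03BA01", "R03BA02", "R03BA05", "R03BA08"})

#: Systemic prednisolone / prednisone — the short-course exacerbation proxy.
PREDNISONE_CODES: frozenset[str] = frozenset({"H02AB06", "H02AB07"})

#: Oral/topical antimycotics: fluconazole, itraconazole, nystatin,
#: amphotericin B, miconazole.
ANTIMYCOTIC_CODES: frozenset[str] = frozenset({
    "J02AC01", "J02AC02", "A07AA02", "A07AA07", "A07AC01",
})

GENDERS = ("male", "female", "unknown")
INDICATIONS = ("asthma", "copd", "bronchitis", "other")
STATUSES = ("sara", "not_interested", "not_now_or_not_offered")


class ValidationError(ValueError):
    """A record or configuration violates a documented invariant."""


def is_valid_atc(code: str) -> bool:
    return bool(ATC_PATTERN.match(code))


@dataclass(frozen=True)
class AtcCodeSets:
    """The drug-class definitions driving every classification step.

    Defaults are the study's code sets; overriding any field re-scopes the
    corresponding outcome (e.g. a different maintenance list).
    """

    r03_maintenance: frozenset[str] = R03_MAINTENANCE
    ics: frozenset[str] = ICS_CODES
    prednisone: frozenset[str] = PREDNISONE_CODES
    antimycotics: frozenset[str] = ANTIMYCOTIC_CODES
    #: values of the optional product-form column that mark nebulizer
    #: products, which are dropped from the adherence analyses
    nebulizer_forms: frozenset[str] = frozenset({"nebulizer"})

    def __post_init__(self) -> None:
        for name in ("r03_maintenance", "ics", "prednisone", "antimycotics"):
            bad = [c for c in getattr(self, name) if not is_valid_atc(c)]
            if bad:
                raise ValidationError(f"{name}: malformed ATC code(s) {bad}")
        if not self.ics <= self.r03_maintenance:
            raise ValidationError("ics must be a subset of r03_maintenance")


@dataclass(frozen=True)
class AtcFlags:
    is_r03_maintenance: bool
    is_ics: bool
    is_prednisone: bool
    is_antimycotic: bool


def classify_atc(atc_code: str, sets: AtcCodeSets | None = None) -> AtcFlags:
    """Membership flags for one ATC code by exact 7-character match.

    Raises :class:`ValidationError` on malformed codes.
    """
    if sets is None:
        sets = AtcCodeSets()
    if not is_valid_atc(atc_code):
        raise ValidationError(f"malformed ATC code: {atc_code!r}")
    return AtcFlags(
        is_r03_maintenance=atc_code in sets.r03_maintenance,
        is_ics=atc_code in sets.ics,
        is_prednisone=atc_code in sets.prednisone,
        is_antimycotic=atc_code in sets.antimycotics,
    )


@dataclass(frozen=True)
class DispensingRecord:
    """One pharmacy dispensing event."""

    patient_id: str
    dispense_date: dt.date
    atc_code: str
    amount: float
    covering_days: int
    daily_dose_mg: float | None = None
    product_form: str | None = None

    def __post_init__(self) -> None:
        if not is_valid_atc(self.atc_code):
            raise ValidationError(f"malformed ATC code: {self.atc_code!r}")
        if self.covering_days < 0:
            raise ValidationError(f"covering_days < 0: {self.covering_days}")
        if self.amount < 0:
            raise ValidationError(f"amount < 0: {self.amount}")


@dataclass(frozen=True)
class PatientRecord:
    """Demographics, indication and study-group registration for one patient."""

    patient_id: str
    birth_year: int
    gender: str
    indication: str
    pharmacy_id: str
    status: str
    registration_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValidationError(f"unknown gender: {self.gender!r}")
        if self.indication not in INDICATIONS:
            raise ValidationError(f"unknown indication: {self.indication!r}")
        if self.status not in STATUSES:
            raise ValidationError(f"unknown status: {self.status!r}")
        if self.status in ("sara", "not_interested") and self.registration_date is None:
            raise ValidationError(
                f"patient {self.patient_id}: status {self.status!r} requires a "
                "registration_date"
            )


@dataclass(frozen=True)
class DateWindow:
    """A closed interval of calendar dates."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"window end {self.end} before start {self.start}")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def __contains__(self, day: dt.date) -> bool:
        return self.start <= day <= self.end


@dataclass(frozen=True)
class CohortEntry:
    """A patient surviving eligibility, with resolved index date and windows.

    ``before_window`` is the 365 days ending the day before the index date;
    ``after_window`` is the 365 days starting on the index date.
    """

    patient_id: str
    group: str  # "sara" | "control"
    index_date: dt.date
    before_window: DateWindow = field(init=False)
    after_window: DateWindow = field(init=False)
    age_at_first_dispensing: int = 0
    gender: str = "unknown"
    indication: str = "other"
    user_type: str = "n/a"  # "new" | "chronic" | "n/a"

    def __post_init__(self) -> None:
        one = dt.timedelta(days=1)
        object.__setattr__(
            self,
            "before_window",
            DateWindow(self.index_date - dt.timedelta(days=365), self.index_date - one),
        )
        object.__setattr__(
            self,
            "after_window",
            DateWindow(self.index_date, self.index_date + dt.timedelta(days=364)),
        )
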