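"""Synthetic patient and dispensing tables with the structure the analysis assumes.

The generator emulates the statistical fingerprint of community-pharmacy
dispensing data around an eHealth-intervention rollout:

* patients are offered the intervention *at* a maintenance-medication refill
  visit, so each patient has an anchor R03 dispensing; their registration is
  recorded the same day or with an administrative delay;
* maintenance refill chains follow the renewal model of
  :mod:`pharmacohort.refill_model` (refills at end of coverage plus a
  Poisson gap, patient-level frailty on the gap mean), generated backward
  from the anchor for the pre-index year and forward for the post-index
  year, with group- and period-specific gap means calibrated so expected
  PDC hits configurable targets exactly;
* short-course oral prednis(ol)one dispensings arrive as per-window Poisson
  events (dose 30/40 mg, 5-14 covering days), alongside non-qualifying
  distractor courses that must not be counted as exacerbations;
* a configurable fraction of patients use an inhaled corticosteroid (ICS)
  as their maintenance product, and antimycotic dispensings arrive as
  per-group, per-period Bernoulli events within the ICS subpopulation;
* distractor content exercises every downstream filter: reliever R03
  dispensings, non-respiratory dispensings, nebulizer-flagged rows,
  minors, non-asthma/COPD indications, and missing participation status.

``simulate_known_effect`` produces data from a null-symmetric configuration
with a stated group-by-time effect injected into adherence and exacerbation
rates, and records the exact ground truth (from the renewal dynamic
program) for parameter-recovery tests.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .datamodel import ValidationError
from .refill_model import (
    DEFAULT_COVERING_DAYS,
    DEFAULT_COVERING_PROBS,
    DEFAULT_FRAILTY_MULTIPLIERS,
    DEFAULT_FRAILTY_PROBS,
    ChainSampler,
    RefillModel,
    calibrate_gap_mean,
    expected_pdc,
)

ICS_PRODUCTS = ("R03BA01", "R03BA02", "R03BA05", "R03BA08")
NON_ICS_MAINTENANCE = ("R03AK06", "R03AK07", "R03AL03", "R03BB04",
                       "R03AC18", "R03AC12")
RELIEVER_CODE = "R03AC02"            # salbutamol: R03 but not maintenance
NEBULIZER_CODE = "R03AL04"
OTHER_CODES = ("N02BE01", "A10BA02")  # paracetamol, metformin
ANTIMYCOTIC_PRODUCTS = ("J02AC01", "J02AC02", "A07AA02", "A07AA07", "A07AC01")
PREDNISONE_PRODUCTS = ("H02AB06", "H02AB07")

_EPOCH = dt.date(1970, 1, 1)


def _to_dates(day_offsets: np.ndarray) -> pd.Series:
    return pd.Series(pd.to_datetime(np.asarray(day_offsets, dtype="int64"),
                                    unit="D", origin="unix"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults reproduce the published cohort's marginal structure: group
    shares, demographics, per-group/period exacerbation rates and adherence
    levels, ICS-use and antimycotic prevalence, and the registration-delay
    behaviour that drives the 30-day eligibility rule.
    """

    n_patients: int = 9452
    seed: int = 0

    # group membership
    p_sara: float = 0.2539
    p_not_interested: float = 0.2573     # remainder: never offered / not now

    # demographics (per analysis group)
    age_mean: dict = field(default_factory=lambda: {"sara": 57.7, "control": 61.9})
    age_sd: dict = field(default_factory=lambda: {"sara": 13.8, "control": 15.3})
    p_female: dict = field(default_factory=lambda: {"sara": 0.6267, "control": 0.5917})
    p_unknown_gender: float = 0.0044
    p_minor: float = 0.01                # under-18 distractors
    indication_probs: dict = field(default_factory=lambda: {
        "asthma": 0.57, "copd": 0.38, "bronchitis": 0.03, "other": 0.02})
    p_missing_status: float = 0.02
    n_pharmacies: int = 382

    # timeline (calendar dates; windows must fit the data horizon)
    index_date_min: dt.date = dt.date(2017, 3, 1)
    index_date_max: dt.date = dt.date(2019, 6, 1)

    # registration behaviour: probability of same-day registration, else
    # a uniform 1..max_registration_delay administrative delay
    p_same_day_registration: float = 0.6
    max_registration_delay: int = 60

    # adherence process: either target PDC means (gap means calibrated via
    # the renewal dynamic program) or explicit per-group/period gap means
    p_new_user: float = 0.196
    pdc_targets: dict = field(default_factory=lambda: {
        "sara": {"before": 70.53, "after": 77.26},
        "control": {"before": 73.29, "after": 77.77}})
    gap_means: dict | None = None
    covering_days_choices: tuple = DEFAULT_COVERING_DAYS
    covering_days_probs: tuple = DEFAULT_COVERING_PROBS
    frailty_multipliers: tuple = DEFAULT_FRAILTY_MULTIPLIERS
    frailty_probs: tuple = DEFAULT_FRAILTY_PROBS

    # exacerbation process (qualifying courses / year)
    exacerbation_rate: dict = field(default_factory=lambda: {
        "sara": {"before": 0.68, "after": 0.73},
        "control": {"before": 0.67, "after": 0.82}})
    distractor_prednisone_rate: float = 0.15   # non-qualifying courses / year

    # ICS use and antimycotics
    p_ics_user: float = 0.247
    p_antimycotic: dict = field(default_factory=lambda: {
        "sara": {"before": 0.0543, "after": 0.0639},
        "control": {"before": 0.0469, "after": 0.0609}})
    p_antimycotic_background: float = 0.02     # non-ICS users, per 2 years

    # distractor dispensing intensity (events / year)
    reliever_rate: float = 1.2
    other_medication_rate: float = 1.5
    p_nebulizer_user: float = 0.05
    nebulizer_interval_days: int = 90

    def __post_init__(self) -> None:
        probs = [self.p_sara, self.p_not_interested, self.p_new_user,
                 self.p_ics_user, self.p_same_day_registration,
                 self.p_missing_status, self.p_unknown_gender, self.p_minor,
                 self.p_nebulizer_user, self.p_antimycotic_background]
        probs += [p for g in self.p_female for p in [self.p_female[g]]]
        probs += [p for g in self.p_antimycotic for p in
                  self.p_antimycotic[g].values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")
        if any(r < 0 for g in self.exacerbation_rate
               for r in self.exacerbation_rate[g].values()):
            raise ValidationError("exacerbation rates must be >= 0")
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")

    def refill_models(self) -> dict:
        """Group/period refill models: calibrated to the PDC targets, or
        built from explicit ``gap_means`` when given."""
        if self.gap_means is not None:
            return {
                group: {period: RefillModel(
                    gap_mean=per[period],
                    covering_days=self.covering_days_choices,
                    covering_probs=self.covering_days_probs,
                    frailty_multipliers=self.frailty_multipliers,
                    frailty_probs=self.frailty_probs)
                    for period in ("before", "after")}
                for group, per in self.gap_means.items()
            }
        out: dict = {}
        for group, per in self.pdc_targets.items():
            out[group] = {
                period: _calibrated(per[period], period,
                                    self.covering_days_choices,
                                    self.covering_days_probs,
                                    self.frailty_multipliers,
                                    self.frailty_probs)
                for period in ("before", "after")
            }
        return out


@lru_cache(maxsize=64)
def _calibrated(target: float, period: str, cd: tuple, cp: tuple,
                fm: tuple, fp: tuple) -> RefillModel:
    return calibrate_gap_mean(target, period, covering_days=cd,
                              covering_probs=cp, frailty_multipliers=fm,
                              frailty_probs=fp)


def _poisson_event_days(rng: np.random.Generator, rate_per_year: float,
                        start: int, end: int) -> np.ndarray:
    """Uniformly placed event days for a Poisson count on [start, end]."""
    n_days = end - start + 1
    n = rng.poisson(rate_per_year * n_days / 365.0)
    if n == 0:
        return np.empty(0, dtype=int)
    return start + rng.integers(0, n_days, size=n)


class _Rows:
    """Column-wise accumulator for dispensing rows."""

    def __init__(self) -> None:
        self.patient_id: list = []
        self.day: list = []
        self.atc: list = []
        self.amount: list = []
        self.covering: list = []
        self.dose: list = []
        self.form: list = []

    def add(self, pid: str, days, atc: str, covering, amount=None,
            dose=None, form=None) -> None:
        day_list = days.tolist() if isinstance(days, np.ndarray) else [days]
        n = len(day_list)
        if n == 0:
            return
        cover_list = (covering.tolist() if isinstance(covering, np.ndarray)
                      else [covering] * n)
        self.patient_id.extend([pid] * n)
        self.day.extend(day_list)
        self.atc.extend([atc] * n)
        self.covering.extend(cover_list)
        self.amount.extend(cover_list if amount is None else [amount] * n)
        self.dose.extend([np.nan if dose is None else dose] * n)
        self.form.extend([form] * n)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": self.patient_id,
            "dispense_date": _to_dates(np.asarray(self.day)),
            "atc_code": self.atc,
            "amount": np.asarray(self.amount, dtype=float),
            "covering_days": np.asarray(self.covering, dtype=int),
            "daily_dose_mg": np.asarray(self.dose, dtype=float),
            "product_form": pd.array(self.form, dtype="string"),
        })


def _draw_qualifying_course(rng: np.random.Generator) -> tuple[int, int]:
    """(daily_dose_mg, covering_days) satisfying the exacerbation rule."""
    return int(rng.choice((30, 40))), int(rng.integers(5, 15))


def _draw_distractor_course(rng: np.random.Generator) -> tuple[int, int]:
    """A prednisone course violating the dose or duration rule."""
    if rng.random() < 0.5:
        dose = int(rng.choice((5, 10, 25, 60)))
        days = int(rng.integers(5, 15))
    else:
        dose = int(rng.choice((30, 40)))
        days = int(rng.choice(np.concatenate([np.arange(1, 5),
                                              np.arange(15, 22)])))
    return dose, days


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (patients, dispensings) tables under ``config``.

    Deterministic given ``config`` (including its seed): identical inputs
    give identical tables.
    """
    patients, dispensings, _ = _simulate(config)
    return patients, dispensings


def simulate_known_effect(config: SimulationConfig,
                          pdc_uplift_sara: float = 0.0,
                          exac_uplift_diff: float = 0.0,
                          base_pdc_before: float = 72.0,
                          base_pdc_gain: float = 4.48,
                          base_exac_rate: float = 0.675,
                          base_exac_drift: float = 0.15,
                          ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Data from a symmetric configuration with known injected effects.

    Both groups share the pre-index adherence and exacerbation processes;
    the post-index control process drifts by ``base_pdc_gain`` PDC points
    and ``base_exac_drift`` events/year, and the intervention group
    additionally moves by ``pdc_uplift_sara`` points (up) and
    ``exac_uplift_diff`` events/year (down). Registration is same-day and
    reliever/other-medication distractors are disabled so the injected
    group-by-time contrast is exactly the estimand of the downstream
    difference-in-differences (see docs/methods.md).

    Returns (patients, dispensings, truth) where ``truth`` records the
    injected effects and the exact per-group/period expectations.
    """
    targets = {
        "control": {"before": base_pdc_before,
                    "after": base_pdc_before + base_pdc_gain},
        "sara": {"before": base_pdc_before,
                 "after": base_pdc_before + base_pdc_gain + pdc_uplift_sara},
    }
    rates = {
        "control": {"before": base_exac_rate,
                    "after": base_exac_rate + base_exac_drift},
        "sara": {"before": base_exac_rate,
                 "after": base_exac_rate + base_exac_drift - exac_uplift_diff},
    }
    if rates["sara"]["after"] < 0:
        raise ValidationError("exac_uplift_diff yields a negative rate")
    cfg = replace(config,
                  pdc_targets=targets,
                  exacerbation_rate=rates,
                  p_same_day_registration=1.0,
                  max_registration_delay=0,
                  reliever_rate=0.0,
                  other_medication_rate=0.0,
                  p_nebulizer_user=0.0,
                  p_missing_status=0.0,
                  p_minor=0.0,
                  indication_probs={"asthma": 0.6, "copd": 0.4,
                                    "bronchitis": 0.0, "other": 0.0})
    patients, dispensings, models = _simulate(cfg)
    truth = {
        "pdc_uplift_sara": pdc_uplift_sara,
        "exac_did_sara_minus_control": -exac_uplift_diff,
        "expected_pdc": {g: {p: expected_pdc(models[g][p], p)
                             for p in ("before", "after")}
                         for g in ("sara", "control")},
        "exacerbation_rate": rates,
        "n_patients": cfg.n_patients,
        "seed": cfg.seed,
    }
    return patients, dispensings, truth


def _simulate(config: SimulationConfig
              ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    rng = np.random.default_rng(config.seed)
    sampler = ChainSampler(rng)
    models = config.refill_models()

    anchor_lo = (config.index_date_min - _EPOCH).days
    anchor_hi = (config.index_date_max - _EPOCH).days

    indication_names = list(config.indication_probs)
    indication_p = np.asarray([config.indication_probs[k]
                               for k in indication_names], dtype=float)
    indication_p = indication_p / indication_p.sum()

    rows = _Rows()
    pat: dict[str, list] = {k: [] for k in (
        "patient_id", "birth_year", "gender", "indication", "pharmacy_id",
        "status", "registration_date")}
    reg_days: list = []

    n = config.n_patients
    u_status = rng.random(n)
    anchors = rng.integers(anchor_lo, anchor_hi + 1, size=n)
    indications = rng.choice(indication_names, size=n, p=indication_p)
    pharmacies = rng.integers(1, config.n_pharmacies + 1, size=n)

    for i in range(n):
        pid = f"P{i + 1:06d}"
        anchor = int(anchors[i])
        if u_status[i] < config.p_sara:
            status, group = "sara", "sara"
        elif u_status[i] < config.p_sara + config.p_not_interested:
            status, group = "not_interested", "control"
        else:
            status, group = "not_now_or_not_offered", "control"
        if rng.random() < config.p_missing_status:
            status = None

        # demographics
        if rng.random() < config.p_minor:
            age = int(rng.integers(8, 17))
        else:
            age = int(np.clip(round(rng.normal(config.age_mean[group],
                                               config.age_sd[group])), 18, 99))
        g = rng.random()
        if g < config.p_unknown_gender:
            gender = "unknown"
        elif g < config.p_unknown_gender + config.p_female[group]:
            gender = "female"
        else:
            gender = "male"
        anchor_year = (_EPOCH + dt.timedelta(days=anchor)).year
        birth_year = anchor_year - age

        # registration
        if rng.random() < config.p_same_day_registration or \
                config.max_registration_delay == 0:
            delay = 0
        else:
            delay = int(rng.integers(1, config.max_registration_delay + 1))
        reg_day = anchor + delay

        # maintenance product and refill chains
        ics_user = rng.random() < config.p_ics_user
        if ics_user:
            product = str(rng.choice(ICS_PRODUCTS))
        else:
            product = str(rng.choice(NON_ICS_MAINTENANCE))
        frailty = float(rng.choice(config.frailty_multipliers,
                                   p=config.frailty_probs))
        new_user = rng.random() < config.p_new_user

        before_start, after_end = anchor - 365, anchor + 364
        if new_user:
            # no R03 before the anchor; an unrelated dispensing predates
            # the 2-year window so the data-completeness rule can pass
            early = anchor - 366 - int(rng.integers(0, 300))
            rows.add(pid, np.asarray([early]), str(rng.choice(OTHER_CODES)), 10)
        else:
            b_days, b_cov = sampler.sample_chain_backward(
                models[group]["before"], frailty, anchor, before_start)
            rows.add(pid, b_days, product, b_cov)
        f_days, f_cov = sampler.sample_chain(
            models[group]["after"], frailty, anchor, after_end)
        rows.add(pid, f_days, product, f_cov)

        # exacerbation proxy: qualifying prednisone courses
        for period, (w0, w1) in (("before", (before_start, anchor - 1)),
                                 ("after", (anchor, after_end))):
            rate = config.exacerbation_rate[group][period]
            for day in _poisson_event_days(rng, rate, w0, w1):
                dose, days = _draw_qualifying_course(rng)
                rows.add(pid, np.asarray([day]),
                         str(rng.choice(PREDNISONE_PRODUCTS)), days,
                         amount=days, dose=dose)
        # non-qualifying distractor courses
        for day in _poisson_event_days(rng, config.distractor_prednisone_rate,
                                       before_start, after_end):
            dose, days = _draw_distractor_course(rng)
            rows.add(pid, np.asarray([day]),
                     str(rng.choice(PREDNISONE_PRODUCTS)), days,
                     amount=days, dose=dose)

        # antimycotics
        if ics_user:
            for period, (w0, w1) in (("before", (before_start, anchor - 1)),
                                     ("after", (anchor, after_end))):
                if rng.random() < config.p_antimycotic[group][period]:
                    day = int(rng.integers(w0, w1 + 1))
                    rows.add(pid, np.asarray([day]),
                             str(rng.choice(ANTIMYCOTIC_PRODUCTS)), 7)
        elif rng.random() < config.p_antimycotic_background:
            day = int(rng.integers(before_start, after_end + 1))
            rows.add(pid, np.asarray([day]),
                     str(rng.choice(ANTIMYCOTIC_PRODUCTS)), 7)

        # distractors: relievers, unrelated medication, nebulizer rows
        if config.reliever_rate > 0 and not new_user:
            rows.add(pid, _poisson_event_days(rng, config.reliever_rate,
                                              before_start, after_end),
                     RELIEVER_CODE, 0)
        if config.other_medication_rate > 0:
            rows.add(pid, _poisson_event_days(
                rng, config.other_medication_rate, before_start - 200,
                after_end + 200), str(rng.choice(OTHER_CODES)), 10)
        if rng.random() < config.p_nebulizer_user:
            neb_days = np.arange(before_start + int(rng.integers(0, 60)),
                                 after_end, config.nebulizer_interval_days)
            rows.add(pid, neb_days, NEBULIZER_CODE,
                     config.nebulizer_interval_days, form="nebulizer")

        pat["patient_id"].append(pid)
        pat["birth_year"].append(birth_year)
        pat["gender"].append(gender)
        pat["indication"].append(indications[i])
        pat["pharmacy_id"].append(f"PH{pharmacies[i]:03d}")
        pat["status"].append(status)
        reg_days.append(reg_day)

    patients = pd.DataFrame({
        "patient_id": pat["patient_id"],
        "birth_year": np.asarray(pat["birth_year"], dtype=int),
        "gender": pat["gender"],
        "indication": pat["indication"],
        "pharmacy_id": pat["pharmacy_id"],
        "status": pd.array(pat["status"], dtype="string"),
        "registration_date": _to_dates(np.asarray(reg_days)),
    })
    dispensings = rows.frame().sort_values(
        ["patient_id", "dispense_date", "atc_code"], kind="stable",
    ).reset_index(drop=True)
    return patients, dispensings, models
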