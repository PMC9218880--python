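"""End-to-end orchestration: data in, cohort, outcomes, statistics, tables.

``run_pipeline`` composes the stage functions exactly as the numbered
analysis drivers do, so a pipeline run equals the composition of the
individually invoked stages on the same inputs. Zero-configuration
defaults reproduce the study's stated rules (365-day windows, 30-day
registration rule, >= 3 maintenance dispensings, PDC cutoff 80, 30/40 mg
for 5-14 days).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .adherence import adherence_outcomes, summarize_adherence
from .antimycotic import antimycotic_outcomes, antimycotic_prevalence
from .cohort import apply_eligibility, classify_user_type, FilterTrace
from .datamodel import AtcCodeSets
from .exacerbation import count_exacerbations, summarize_exacerbations
from .glmm import glmm_antimycotics, GlmmResult
from .simulate import SimulationConfig, simulate_cohort
from .stats import (AncovaResult, TTestResult, ancova_screen,
                    demographics_table, diff_score_ttest, new_user_ttest)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: input source, thresholds, output location."""

    patients_path: str | None = None
    dispensings_path: str | None = None
    simulate: bool = False
    sim_config: SimulationConfig | None = None
    code_sets: AtcCodeSets = field(default_factory=AtcCodeSets)
    max_registration_gap: int = 30
    min_dispensings: int = 3
    adherence_cutoff: float = 80.0
    subgroup: str = "all"               # all | asthma | copd
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subgroup not in ("all", "asthma", "copd"):
            raise ValueError(f"unknown subgroup {self.subgroup!r}")
        if not self.simulate and not (self.patients_path
                                      and self.dispensings_path):
            raise ValueError("need input paths or simulate=True")


@dataclass
class PipelineReport:
    """All stage outputs of one run."""

    cohort: pd.DataFrame
    filter_trace: FilterTrace
    demographics: pd.DataFrame
    exacerbation_outcomes: pd.DataFrame
    exacerbation_summary: pd.DataFrame
    exacerbation_test: TTestResult | None
    adherence_outcomes: pd.DataFrame
    adherence_summary: pd.DataFrame
    adherence_chronic_test: TTestResult | None
    adherence_new_user_test: TTestResult | None
    adherence_ancova: AncovaResult | None
    antimycotic_outcomes: pd.DataFrame
    antimycotic_prevalence: pd.DataFrame
    antimycotic_glmm: GlmmResult | None


def _load_inputs(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.simulate:
        sim = config.sim_config or SimulationConfig(seed=config.seed)
        if sim.seed != config.seed and config.seed != 0:
            sim = dataclasses.replace(sim, seed=config.seed)
        return simulate_cohort(sim)
    patients = io.read_patients(config.patients_path)
    dispensings = io.read_dispensings(config.dispensings_path)
    return patients, dispensings


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run every stage; deterministic given the seed; logs row counts."""
    patients, dispensings = _load_inputs(config)
    logger.info("stage=input patients=%d dispensings=%d",
                len(patients), len(dispensings))

    cohort, trace = apply_eligibility(
        patients, dispensings, max_registration_gap=config.max_registration_gap)
    cohort = classify_user_type(cohort, dispensings)
    if config.subgroup != "all":
        cohort = cohort.loc[cohort["indication"] == config.subgroup]
        cohort = cohort.reset_index(drop=True)
    logger.info("stage=cohort input=%d final=%d excluded=%s",
                trace.n_input, len(cohort), trace.counts)

    demo = demographics_table(cohort)

    exac = count_exacerbations(cohort, dispensings, config.code_sets)
    exac_summary = summarize_exacerbations(exac)
    exac_test = None
    sara_d = exac.loc[exac["group"] == "sara", "difference"]
    ctrl_d = exac.loc[exac["group"] == "control", "difference"]
    if len(sara_d) >= 2 and len(ctrl_d) >= 2:
        exac_test = diff_score_ttest(sara_d, ctrl_d)
    logger.info("stage=exacerbation patients=%d", len(exac))

    adh = adherence_outcomes(cohort, dispensings, config.code_sets,
                             min_dispensings=config.min_dispensings,
                             cutoff=config.adherence_cutoff)
    adh_summary = summarize_adherence(adh)
    chronic = adh.loc[adh["user_type"] == "chronic"].dropna(
        subset=["difference"])
    new = adh.loc[adh["user_type"] == "new"].dropna(subset=["pdc_after"])
    chronic_test = new_test = ancova = None
    if chronic.groupby("group").size().ge(2).all() and \
            chronic["group"].nunique() == 2:
        chronic_test = diff_score_ttest(
            chronic.loc[chronic["group"] == "sara", "difference"],
            chronic.loc[chronic["group"] == "control", "difference"])
        try:
            ancova = ancova_screen(chronic["difference"], chronic["group"],
                                   chronic["age_at_first_dispensing"],
                                   chronic["gender"])
        except ValueError as exc:
            logger.warning("ancova screen skipped: %s", exc)
    if new["group"].nunique() == 2 and new.groupby("group").size().ge(2).all():
        new_test = new_user_ttest(
            new.loc[new["group"] == "sara", "pdc_after"],
            new.loc[new["group"] == "control", "pdc_after"])
    logger.info("stage=adherence chronic=%d new=%d excluded_min_disp=%d",
                len(chronic), len(new),
                adh.attrs.get("n_excluded_min_dispensings", 0))

    anti = antimycotic_outcomes(cohort, dispensings, config.code_sets)
    anti_prev = antimycotic_prevalence(anti)
    glmm = None
    if len(anti) >= 20 and anti["group"].nunique() == 2:
        glmm = glmm_antimycotics(anti)
    logger.info("stage=antimycotic ics_users=%d", len(anti))

    report = PipelineReport(
        cohort=cohort, filter_trace=trace, demographics=demo,
        exacerbation_outcomes=exac, exacerbation_summary=exac_summary,
        exacerbation_test=exac_test,
        adherence_outcomes=adh, adherence_summary=adh_summary,
        adherence_chronic_test=chronic_test,
        adherence_new_user_test=new_test, adherence_ancova=ancova,
        antimycotic_outcomes=anti, antimycotic_prevalence=anti_prev,
        antimycotic_glmm=glmm)
    if config.output_dir:
        _write_report(report, Path(config.output_dir))
    return report


def _ttest_frame(result: TTestResult | None, label: str) -> pd.DataFrame:
    if result is None:
        return pd.DataFrame([{"outcome": label, "available": False}])
    return pd.DataFrame([{
        "outcome": label, "available": True,
        "mean_diff_sara": result.mean_diff_sara,
        "mean_diff_control": result.mean_diff_control,
        "t": result.t_statistic, "df": result.df, "p": result.p_value,
        "ci_low": result.ci95[0], "ci_high": result.ci95[1],
        "cohen_d": result.cohen_d,
        "n_sara": result.n_sara, "n_control": result.n_control}])


def _write_report(report: PipelineReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_table(report.cohort, outdir / "cohort.csv")
    io.write_table(report.filter_trace.to_frame(), outdir / "filter_trace.csv")
    io.write_table(report.demographics, outdir / "demographics.csv")
    io.write_table(report.exacerbation_summary,
                   outdir / "exacerbation_summary.csv")
    io.write_table(report.adherence_summary, outdir / "adherence_summary.csv")
    io.write_table(report.antimycotic_prevalence,
                   outdir / "antimycotic_prevalence.csv")
    tests = pd.concat([
        _ttest_frame(report.exacerbation_test, "exacerbation_difference"),
        _ttest_frame(report.adherence_chronic_test,
                     "adherence_difference_chronic"),
        _ttest_frame(report.adherence_new_user_test, "adherence_after_new"),
    ], ignore_index=True)
    io.write_table(tests, outdir / "group_tests.csv")
    if report.antimycotic_glmm is not None:
        g = report.antimycotic_glmm
        frame = pd.DataFrame({
            "term": g.params.index, "estimate": g.params.values,
            "se": g.bse.values, "z": g.z_values.values,
            "p": g.p_values.values})
        frame["random_intercept_sd"] = g.random_intercept_sd
        io.write_table(frame, outdir / "antimycotic_glmm.csv")
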