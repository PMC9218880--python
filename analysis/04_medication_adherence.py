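"""Medication adherence: proportion of days covered, "at least one" method.

Computes per-patient PDCs for maintenance R03 medication in both analysis
years, summarizes chronic users by group and period, compares chronic
difference scores and new users' post-index PDC between groups, and
screens age/gender as covariates.
"""

from pathlib import Path

import pandas as pd

from pharmacohort import io
from pharmacohort.adherence import adherence_outcomes, summarize_adherence
from pharmacohort.stats import ancova_screen, diff_score_ttest, new_user_ttest

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    cohort = pd.read_csv(DATA / "cohort.csv", parse_dates=[
        "index_date", "before_start", "before_end", "after_start",
        "after_end"])
    dispensings = io.read_dispensings(DATA / "dispensings.csv")

    outcomes = adherence_outcomes(cohort, dispensings)
    summary = summarize_adherence(outcomes)
    io.write_table(summary, RESULTS / "adherence_summary.csv")
    print(summary.to_string(index=False))
    print(f"\nexcluded for < 3 maintenance dispensings: "
          f"{outcomes.attrs['n_excluded_min_dispensings']}")

    chronic = outcomes.loc[outcomes["user_type"] == "chronic"].dropna(
        subset=["difference"])
    test = diff_score_ttest(
        chronic.loc[chronic["group"] == "sara", "difference"],
        chronic.loc[chronic["group"] == "control", "difference"])
    print(f"\nchronic users, difference-score t test: t({test.df}) = "
          f"{test.t_statistic:.2f}, p = {test.p_value:.4f}, d = "
          f"{test.cohen_d:.3f}")

    new = outcomes.loc[outcomes["user_type"] == "new"].dropna(
        subset=["pdc_after"])
    nt = new_user_ttest(new.loc[new["group"] == "sara", "pdc_after"],
                        new.loc[new["group"] == "control", "pdc_after"])
    print(f"new users, post-index PDC t test: t({nt.df}) = "
          f"{nt.t_statistic:.2f}, p = {nt.p_value:.4f}")

    screen = ancova_screen(chronic["difference"], chronic["group"],
                           chronic["age_at_first_dispensing"],
                           chronic["gender"])
    print(f"covariate screen p-values: {screen.covariate_p_values}; "
          f"significant: {screen.significant_covariates or 'none'}")
    for level, res in screen.stratified.items():
        print(f"  stratified ({level}): t({res.df}) = "
              f"{res.t_statistic:.2f}, p = {res.p_value:.4f}")


if __name__ == "__main__":
    main()
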