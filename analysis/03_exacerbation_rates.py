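"""Exacerbation-rate outcome: short oral prednis(ol)one courses per year.

Counts qualifying 30/40 mg, 5-14 day courses per patient and window,
summarizes rates by group and period, and compares the per-patient
difference scores between groups with the pooled t test.
"""

from pathlib import Path

import pandas as pd

from pharmacohort import io
from pharmacohort.exacerbation import (count_exacerbations,
                                       summarize_exacerbations)
from pharmacohort.stats import diff_score_ttest

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    cohort = pd.read_csv(DATA / "cohort.csv", parse_dates=[
        "index_date", "before_start", "before_end", "after_start",
        "after_end"])
    dispensings = io.read_dispensings(DATA / "dispensings.csv")

    outcomes = count_exacerbations(cohort, dispensings)
    summary = summarize_exacerbations(outcomes)
    io.write_table(summary, RESULTS / "exacerbation_summary.csv")
    print(summary.to_string(index=False))

    test = diff_score_ttest(
        outcomes.loc[outcomes["group"] == "sara", "difference"],
        outcomes.loc[outcomes["group"] == "control", "difference"])
    print(f"\ndifference-score t test (control - intervention): "
          f"t({test.df}) = {test.t_statistic:.2f}, p = {test.p_value:.4f}, "
          f"95% CI [{test.ci95[0]:.3f}, {test.ci95[1]:.3f}], "
          f"d = {test.cohen_d:.3f}")


if __name__ == "__main__":
    main()
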