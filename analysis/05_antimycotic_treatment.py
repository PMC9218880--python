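"""Antimycotic co-treatment among inhaled-corticosteroid users.

Builds the binary per-window antimycotic outcome in the ICS
subpopulation, reports the group-by-period prevalence table, and fits the
random-intercept logistic model with the group-by-time interaction as the
headline contrast.
"""

from pathlib import Path

import pandas as pd

from pharmacohort import io
from pharmacohort.antimycotic import (antimycotic_outcomes,
                                      antimycotic_prevalence)
from pharmacohort.glmm import glmm_antimycotics

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    cohort = pd.read_csv(DATA / "cohort.csv", parse_dates=[
        "index_date", "before_start", "before_end", "after_start",
        "after_end"])
    dispensings = io.read_dispensings(DATA / "dispensings.csv")

    outcomes = antimycotic_outcomes(cohort, dispensings)
    prevalence = antimycotic_prevalence(outcomes)
    io.write_table(prevalence, RESULTS / "antimycotic_prevalence.csv")
    print(f"ICS subpopulation: {len(outcomes)} patients")
    print(prevalence.to_string(index=False))

    model = glmm_antimycotics(outcomes)
    table = pd.DataFrame({"estimate": model.params, "se": model.bse,
                          "z": model.z_values, "p": model.p_values})
    io.write_table(table.reset_index(names="term"),
                   RESULTS / "antimycotic_glmm.csv")
    print("\nrandom-intercept logistic regression:")
    print(table.round(3).to_string())
    print(f"random-intercept SD: {model.random_intercept_sd:.3f}")
    print(f"group-by-time interaction p = {model.interaction_p_value:.3f}")


if __name__ == "__main__":
    main()
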