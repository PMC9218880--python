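"""Resolve index dates, apply the five eligibility criteria, classify users.

Reads the raw tables from 01, builds the analysis cohort, and reports the
participant flow (how many patients each criterion excluded) plus the
demographic contrast between the intervention and control groups.
"""

from pathlib import Path

from pharmacohort import io
from pharmacohort.cohort import apply_eligibility, classify_user_type
from pharmacohort.stats import demographics_table

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    patients = io.read_patients(DATA / "patients.csv")
    dispensings = io.read_dispensings(DATA / "dispensings.csv")
    cohort, trace = apply_eligibility(patients, dispensings)
    cohort = classify_user_type(cohort, dispensings)

    io.write_table(cohort, DATA / "cohort.csv")
    io.write_table(trace.to_frame(), RESULTS / "filter_trace.csv")
    demo = demographics_table(cohort)
    io.write_table(demo, RESULTS / "demographics.csv")

    print(trace.to_frame().to_string(index=False))
    n_new = (cohort["user_type"] == "new").sum()
    print(f"\ncohort: {trace.n_final}/{trace.n_input} patients "
          f"({n_new} new users, {trace.n_final - n_new} chronic)")
    share = cohort.groupby("group").size()
    print(f"groups: {share.to_dict()}")


if __name__ == "__main__":
    main()
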