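"""Generate the synthetic study population.

Writes the two raw input tables (patients, dispensings) for a cohort at
the published study's scale (9452 patients) to scratch/data/, where the
later numbered scripts pick them up. The generator's defaults encode the
study conditions: group shares, demographics, per-group/period
exacerbation rates, adherence targets and antimycotic prevalence.
"""

from pathlib import Path

from pharmacohort import io
from pharmacohort.simulate import SimulationConfig, simulate_cohort

SEED = 20
OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main() -> None:
    config = SimulationConfig(n_patients=9452, seed=SEED)
    patients, dispensings = simulate_cohort(config)
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_patients(patients, OUT / "patients.csv")
    io.write_dispensings(dispensings, OUT / "dispensings.csv")
    print(f"simulated {len(patients)} patients, {len(dispensings)} "
          f"dispensing records (seed {SEED})")
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
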