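"""Simulate the study cohort: 161 subjects, 8 diagnosis groups, 3 dose arms.

Draws the default synthetic study population (group truth distributions
calibrated to the published group summaries), plus the 204 concomitant
whole-blood/plasma sample pairs. Bulky per-sample data goes to scratch/;
the small design summary goes to results/.
"""

from pathlib import Path

import pandas as pd

from csfclear import io
from csfclear.simulate import (
    default_study_config,
    pairs_to_frame,
    simulate_cohort,
    simulate_paired_blood,
    truth_table,
)

SEED = 20220701  # fixed study-simulation seed for the whole analysis chain

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    config = default_study_config(seed=SEED)
    subjects, truth = simulate_cohort(config)
    io.write_subjects(subjects, SCRATCH / "cohort.csv")
    truth_table(subjects, truth).to_csv(SCRATCH / "truth.csv", index=False)
    config.to_yaml(SCRATCH / "config.yaml")

    import numpy as np

    pairs = simulate_paired_blood(subjects, rng=np.random.default_rng(SEED + 1))
    pairs_to_frame(pairs).to_csv(SCRATCH / "paired_blood.csv", index=False)

    design = (
        io.subjects_to_frame(subjects)
        .groupby(["group", "dose_mmol"])
        .agg(n_subjects=("subject_id", "nunique"), n_samples=("time_h", "size"))
        .reset_index()
    )
    design.to_csv(RESULTS / "cohort_design.csv", index=False)

    n_obs = [s.n_obs for s in subjects]
    print(f"simulated {len(subjects)} subjects, {sum(n_obs)} samples "
          f"(per subject: mean {sum(n_obs)/len(n_obs):.1f}, "
          f"range {min(n_obs)}-{max(n_obs)})")
    print(f"paired whole-blood/plasma samples: {len(pairs)}")
    print(f"wrote {SCRATCH / 'cohort.csv'} and {RESULTS / 'cohort_design.csv'}")


if __name__ == "__main__":
    main()
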