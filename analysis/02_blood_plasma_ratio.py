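"""Plasma-to-whole-blood partition ratio by regression through the origin.

Reads the paired samples simulated by 01_simulate_cohort.py, fits
plasma = slope x whole_blood (no intercept), and writes the fitted ratio.
The configured truth is 1.795 (gadobutrol is excluded from erythrocytes, so
plasma exceeds whole blood by roughly 1/(1 - hematocrit)).
"""

import json
from pathlib import Path

import pandas as pd

from csfclear.metrics import fit_blood_plasma_ratio

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main() -> None:
    pairs = pd.read_csv(SCRATCH / "paired_blood.csv")
    fit = fit_blood_plasma_ratio(
        list(zip(pairs["whole_blood_uM"], pairs["plasma_uM"]))
    )
    out = {
        "slope_plasma_per_whole_blood": fit.slope,
        "r_squared_adjusted": fit.r_squared_adjusted,
        "n_pairs": fit.n_pairs,
    }
    RESULTS.mkdir(parents=True, exist_ok=True)
    (RESULTS / "blood_plasma_ratio.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"plasma = {fit.slope:.3f} x whole blood "
          f"(adjusted R^2 = {fit.r_squared_adjusted:.4f}, n = {fit.n_pairs})")


if __name__ == "__main__":
    main()
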