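"""Population model development: split, candidate structures, final fit.

Splits the cohort 80/20 (all >6-sample profiles into development), fits
one- and two-compartment candidates on the development set, selects by the
development-set relative RMSE%, then refits the selected structure on the
complete dataset and writes the fitted model plus selection/diagnostic
tables. This is the long step (~10 min on one core at the full 161-subject
design).
"""

import json
from pathlib import Path

import pandas as pd

from csfclear import io
from csfclear.model import AssayErrorModel
from csfclear.npml import FitConfig, fit, model_to_json, posterior_individual
from csfclear.analysis import (
    information_criteria,
    prediction_diagnostics,
    split_dev_validation,
)

SEED = 20220701

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main() -> None:
    subjects = io.read_subjects(SCRATCH / "cohort.csv")
    error = AssayErrorModel()
    dev, val = split_dev_validation(subjects, 0.8, seed=SEED)
    print(f"development {len(dev)} subjects / validation {len(val)} subjects")

    rows = []
    for structure in ("one_compartment", "two_compartment"):
        model = fit(dev, error, FitConfig(structure=structure, seed=SEED))
        posts = {s.id: posterior_individual(s, model, error) for s in dev}
        diag = prediction_diagnostics(dev, posts, model=model)
        val_posts = {s.id: posterior_individual(s, model, error) for s in val}
        val_diag = prediction_diagnostics(val, val_posts)
        ic = information_criteria(model, dev)
        rows.append(
            {
                "structure": structure,
                "rmse_pct_dev": diag.rmse_pct,
                "rmse_pct_validation": val_diag.rmse_pct,
                "r_squared": diag.r_squared,
                "slope": diag.slope,
                "AIC": ic["AIC"],
                "BIC": ic["BIC"],
                "loglik": model.loglik,
                "n_support": len(model.support),
            }
        )
        print(f"{structure}: dev RMSE% {diag.rmse_pct:.1f}, "
              f"validation RMSE% {val_diag.rmse_pct:.1f}, "
              f"AIC {ic['AIC']:.0f}, BIC {ic['BIC']:.0f}")

    scores = pd.DataFrame(rows).sort_values("rmse_pct_dev")
    RESULTS.mkdir(parents=True, exist_ok=True)
    scores.to_csv(RESULTS / "model_selection.csv", index=False)
    selected = scores.iloc[0]["structure"]
    print(f"selected structure: {selected}")

    final = fit(subjects, error, FitConfig(structure=selected, seed=SEED))
    (SCRATCH / "final_model.json").write_text(model_to_json(final))

    posts = {s.id: posterior_individual(s, final, error) for s in subjects}
    diag = prediction_diagnostics(subjects, posts, model=final)
    summary = {
        "structure": selected,
        "n_subjects": len(subjects),
        "mpe_uM": diag.mpe,
        "rmse_uM": diag.rmse,
        "rmse_pct": diag.rmse_pct,
        "obs_vs_pred_slope": diag.slope,
        "obs_vs_pred_r_squared": diag.r_squared,
        "AIC": diag.aic,
        "BIC": diag.bic,
        "n_support": len(final.support),
        "loglik": final.loglik,
    }
    (RESULTS / "final_model_diagnostics.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    diag.residuals.to_csv(SCRATCH / "residuals.csv", index=False)
    print(f"final model on complete dataset: MPE {diag.mpe:+.4f} uM, "
          f"RMSE {diag.rmse:.3f} uM, RMSE% {diag.rmse_pct:.1f}")


if __name__ == "__main__":
    main()
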