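"""Posterior individual PK metrics and the group-level summary table.

For every subject: posterior individual estimate under the final model,
1-minute prediction grid to 72 h, absorption half-life, Tmax, Cmax, Tlag,
AUC0-inf and dose-normalized forms. Writes the tidy per-subject metrics
(scratch) and the group mean +/- SD (CV%) summary (results).
"""

from pathlib import Path

from csfclear import io
from csfclear.model import AssayErrorModel
from csfclear.npml import model_from_json, posterior_individual
from csfclear.analysis import group_summary, metrics_table

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main() -> None:
    subjects = io.read_subjects(SCRATCH / "cohort.csv")
    model = model_from_json((SCRATCH / "final_model.json").read_text())
    error = AssayErrorModel()

    posteriors = {s.id: posterior_individual(s, model, error) for s in subjects}
    metrics = metrics_table(subjects, posteriors)
    metrics.to_csv(SCRATCH / "pk_metrics.csv", index=False)

    summary = group_summary(metrics)
    RESULTS.mkdir(parents=True, exist_ok=True)
    summary.round(2).to_csv(RESULTS / "group_summary.csv", index=False)

    cols = ["t_half_abs_h", "t_max_h", "c_max_dn_uM", "t_lag_h", "auc_dn_uMh"]
    print("group means:")
    shown = summary.set_index("group")
    for group in shown.index:
        vals = "  ".join(
            f"{c.split('_h')[0]}={shown.loc[group, c + '_mean']:.2f}" for c in cols
        )
        print(f"  {group:>10} (n={shown.loc[group, 'n']:>2.0f}): {vals}")


if __name__ == "__main__":
    main()
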