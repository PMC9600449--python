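"""Call CDKN2A loss from amplicon coverage: fit the panel of normals
(median normalization, per-amplicon 99% intervals on log2 scale), apply
the more-than-2-consecutive-amplicons rule to every tumor, and score the
calls against the simulation truth.

Reads results/synthetic/ (regenerating it if absent);
writes results/cnv/.
"""

from pathlib import Path

import pandas as pd

from lymphpanel import io
from lymphpanel.cnv import call_cohort, fit_normal_panel
from lymphpanel.simulate import SimulationConfig, simulate_study

SEED = 7
ROOT = Path(__file__).resolve().parents[1]
SYN = ROOT / "results" / "synthetic"
OUT = ROOT / "results" / "cnv"


def load_inputs():
    if (SYN / "coverage_tumors.tsv").exists():
        panel = io.read_amplicon_panel(SYN / "panel.bed")
        normals = io.read_coverage_matrix(SYN / "coverage_normals.tsv")
        tumors = io.read_coverage_matrix(SYN / "coverage_tumors.tsv")
        truth = pd.read_csv(SYN / "cdkn2a_loss_truth.tsv", sep="\t")
    else:
        study = simulate_study(SimulationConfig(seed=SEED))
        panel, normals, tumors, truth = (
            study.panel, study.normals, study.tumors, study.loss_truth)
    return panel, normals, tumors, truth


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel, normals, tumors, truth = load_inputs()

    model = fit_normal_panel(normals, panel, "CDKN2A", ci_level=0.99)
    calls = call_cohort(tumors, model, consecutive_min=3)
    calls.to_csv(OUT / "cdkn2a_calls.tsv", sep="\t", index=False)

    norm_rows = pd.DataFrame(
        {"amplicon_id": model.amplicon_ids,
         "factor": model.factor,
         "ci_lower": model.ci_lower,
         "ci_upper": model.ci_upper,
         "sd_log2": model.sd_log2})
    norm_rows.to_csv(OUT / "normal_panel_model.tsv", sep="\t", index=False)

    merged = calls.merge(truth, on="sample_id")
    merged["true_loss"] = merged.loss != "none"
    tp = int((merged.loss_called & merged.true_loss).sum())
    fp = int((merged.loss_called & ~merged.true_loss).sum())
    fn = int((~merged.loss_called & merged.true_loss).sum())
    tn = int((~merged.loss_called & ~merged.true_loss).sum())
    merged.to_csv(OUT / "cdkn2a_calls_vs_truth.tsv", sep="\t", index=False)

    print(f"normal panel: {model.n_libraries} libraries, "
          f"{len(model.amplicon_ids)} CDKN2A amplicons, "
          f"99% interval method {model.method}")
    print(f"calls on {len(calls)} tumors: {int(calls.loss_called.sum())} losses called")
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    print(f"against truth: TP {tp}, FP {fp}, FN {fn}, TN {tn} "
          f"-> sensitivity {sens:.2f}, specificity {spec:.2f}")
    missed = merged[~merged.loss_called & merged.true_loss]
    if len(missed):
        print("missed losses (low purity dilutes the dosage signal):")
        print(missed[["sample_id", "loss", "purity", "max_run_below"]]
              .to_string(index=False))
    print(f"wrote cdkn2a_calls.tsv, normal_panel_model.tsv to {OUT}")


if __name__ == "__main__":
    main()
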