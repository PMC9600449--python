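"""Paired primary/relapse analysis on the simulated cohort: classify each
alteration as stable, lost or gained, flag same-gene/different-site
(somatic-hypermutation fingerprint) genes, and tally driver stability.

Reads results/synthetic/ and results/cnv + qc outputs when present
(regenerating in memory otherwise); writes results/paired/.
"""

from pathlib import Path

import pandas as pd

from lymphpanel import io
from lymphpanel.cnv import call_cohort, fit_normal_panel
from lymphpanel.paired import (
    SampleAlterations,
    cohort_paired_summary,
    collect_hotspot_keys,
    compare_pair,
)
from lymphpanel.qc import filter_variants
from lymphpanel.simulate import SimulationConfig, simulate_study

SEED = 7
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "paired"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = simulate_study(SimulationConfig(seed=SEED))

    model = fit_normal_panel(study.normals, study.panel, "CDKN2A")
    cnv_calls = call_cohort(study.tumors, model).set_index("sample_id")

    paired = set(study.paired_patients)
    primary_kept, _ = filter_variants(
        [v for v in study.variants if v.sample_id in paired])
    relapse_kept, _ = filter_variants(study.relapse_variants)

    by_p: dict[str, list] = {pid: [] for pid in paired}
    for v in primary_kept:
        by_p[v.sample_id].append(v)
    by_r: dict[str, list] = {pid: [] for pid in paired}
    for v in relapse_kept:
        by_r[v.sample_id[:-2]].append(v)

    comparisons, samples, rows = [], [], []
    for pid in study.paired_patients:
        p = SampleAlterations(
            pid, variants=by_p[pid],
            losses={"CDKN2A"} if cnv_calls.loc[pid, "loss_called"] else set())
        r = SampleAlterations(
            pid + "-R", variants=by_r[pid],
            losses={"CDKN2A"} if study.relapse_loss[pid + "-R"] else set())
        cmp = compare_pair(pid, p, r)
        comparisons.append(cmp)
        samples.extend([p, r])
        rows.append({
            "patient_id": pid,
            "n_stable": len(cmp.stable),
            "n_lost": len(cmp.lost),
            "n_gained": len(cmp.gained),
            "same_gene_different_site": ";".join(sorted(cmp.same_gene_different_site)),
            **{d: s for d, s in cmp.driver_state.items()},
            "any_driver_stable": cmp.any_driver_stable,
        })
    pd.DataFrame(rows).to_csv(OUT / "paired_comparisons.tsv", sep="\t", index=False)

    hot = collect_hotspot_keys(samples)
    overall = cohort_paired_summary(comparisons, "all", hotspot_keys=hot)
    nondriver = cohort_paired_summary(comparisons, "non_drivers", hotspot_keys=hot)
    overall.per_gene.to_csv(OUT / "per_gene_discrepancies.tsv", sep="\t", index=False)

    fs = overall.fractions
    print(f"{overall.n_patients} paired patients; all alterations pooled: "
          f"{overall.n_stable} stable / {overall.n_lost} lost / "
          f"{overall.n_gained} gained "
          f"({fs[0]:.0%} / {fs[1]:.0%} / {fs[2]:.0%} of {overall.n_total})")
    fn = nondriver.fractions
    print(f"non-driver alterations only: {nondriver.n_stable}/{nondriver.n_total} "
          f"stable ({fn[0]:.0%})")
    print(f"patients with >= 1 stable driver: "
          f"{overall.n_patients_any_driver_stable}/{overall.n_patients}")
    print("most discrepant genes:")
    print(overall.per_gene.head(5).to_string(index=False))
    print(f"wrote paired_comparisons.tsv, per_gene_discrepancies.tsv to {OUT}")


if __name__ == "__main__":
    main()
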