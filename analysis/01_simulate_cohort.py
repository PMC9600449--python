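"""Generate the synthetic study inputs: panel BED, normal/tumor amplicon
coverage, raw variant tables, paired relapse samples and clinical
follow-up. Everything is seeded, so downstream steps can either read the
files written here or regenerate the identical data in memory.

Writes results/synthetic/.
"""

from pathlib import Path

from lymphpanel import io
from lymphpanel.simulate import SimulationConfig, simulate_study

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=SEED)
    study = simulate_study(config)

    io.write_amplicon_panel(study.panel, OUT / "panel.bed")
    io.write_coverage_matrix(study.normals, OUT / "coverage_normals.tsv")
    io.write_coverage_matrix(study.tumors, OUT / "coverage_tumors.tsv")
    study.loss_truth.to_csv(OUT / "cdkn2a_loss_truth.tsv", sep="\t", index=False)
    io.write_variant_table(study.variants, OUT / "variants_primary.tsv")
    study.variant_truth.to_csv(OUT / "variant_truth.tsv", sep="\t", index=False)
    io.write_variant_table(study.relapse_variants, OUT / "variants_relapse.tsv")
    io.write_clinical_table(study.clinical, OUT / "clinical.tsv")

    n_art = int(study.variant_truth.is_artefact.sum())
    print(f"panel: {len(study.panel)} amplicons over {len(study.panel.genes)} genes "
          f"({len(study.panel.gene_index['CDKN2A'])} on CDKN2A)")
    print(f"cohort: {config.n_patients} patients, {config.n_normals} normal libraries, "
          f"{config.n_paired} paired relapses")
    print(f"variants: {len(study.variants)} raw calls "
          f"({n_art} FFPE transition artefacts)")
    print(f"CDKN2A loss simulated in "
          f"{(study.loss_truth.loss != 'none').sum()}/{config.n_patients} tumors")
    print(f"wrote {len(list(OUT.iterdir()))} files to {OUT}")


if __name__ == "__main__":
    main()
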