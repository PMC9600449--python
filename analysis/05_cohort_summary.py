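"""Cohort summarization on the synthetic reconstruction of the published
marginals: gene frequency table, NF-kB pathway aggregate, driver
coverage, mutational-burden dichotomy, oncoprint export, and the MYC
relapse-vs-non-relapse contingency comparison.

Writes results/cohort/.
"""

from pathlib import Path

import pandas as pd

from lymphpanel.cohort import (
    burden_dichotomy,
    driver_coverage,
    format_percent,
    gene_frequency_table,
    group_contingency,
    lymphgen_feature_export,
    oncoprint_matrix,
    pathway_frequency,
)
from lymphpanel.reconstruction import synthetic_reconstruction_cohort

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    profiles = synthetic_reconstruction_cohort()
    n = len(profiles)

    freq = gene_frequency_table(profiles)
    freq.to_csv(OUT / "gene_frequencies.tsv", sep="\t", index=False)
    top = freq.set_index("gene")
    print(f"cohort of {n} synthetic profiles (printed-marginal reconstruction)")
    for gene in ("MYD88", "CD79B", "PIM1", "TBL1XR1", "KMT2D"):
        row = top.loc[gene]
        print(f"  {gene}: {row.n_mutated}/{n} mutated "
              f"({format_percent(row.fraction_mutated)})")
    print(f"  CDKN2A loss: {top.loc['CDKN2A', 'n_loss']}/{n} "
          f"({format_percent(top.loc['CDKN2A', 'n_loss'] / n)})")
    print(f"  MYC rearranged: {top.loc['MYC', 'n_rearranged']}/{n}")

    n_nfkb, f_nfkb = pathway_frequency(profiles)
    print(f"NF-kB pathway (MYD88/CD79B/CARD11/TNFAIP3) mutated: "
          f"{n_nfkb}/{n} ({format_percent(f_nfkb)})")

    n_cov, f_cov, _ = driver_coverage(profiles)
    print(f"driver coverage (MYD88/CD79B mutation and/or CDKN2A loss): "
          f"{n_cov}/{n} ({format_percent(f_cov)})")

    med, _ = burden_dichotomy(profiles)
    burdens = sorted(p.n_pathogenic_mutations for p in profiles)
    print(f"pathogenic mutations per patient: median {med:.0f} "
          f"(range {burdens[0]}-{burdens[-1]})")

    matrix, gene_marg, pat_marg = oncoprint_matrix(profiles)
    matrix.to_csv(OUT / "oncoprint.tsv", sep="\t")

    report_rows = []
    for gene in ("MYC", "TBL1XR1", "KMT2D"):
        res = group_contingency(profiles, gene)
        report_rows.append({"feature": gene,
                            "relapse_with": res.table[0, 0],
                            "relapse_without": res.table[0, 1],
                            "nonrelapse_with": res.table[1, 0],
                            "nonrelapse_without": res.table[1, 1],
                            "chi2": res.chi2, "p": res.p})
        print(f"{gene} relapse vs non-relapse: {res.table[0,0]}/{res.table[0].sum()} "
              f"vs {res.table[1,0]}/{res.table[1].sum()} "
              f"(chi-square {res.chi2:.2f}, p = {res.p:.3f})")
    pd.DataFrame(report_rows).to_csv(OUT / "contingency.tsv", sep="\t", index=False)

    lymphgen_feature_export(profiles).to_csv(
        OUT / "classifier_feature_export.tsv", sep="\t", index=False)
    print(f"wrote gene_frequencies.tsv, oncoprint.tsv, contingency.tsv, "
          f"classifier_feature_export.tsv to {OUT}")


if __name__ == "__main__":
    main()
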