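"""Cohort-level summarization: per-patient alteration profiles, gene
frequencies, driver coverage, oncoprint export and relapse-group
contingency comparisons."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ClinicalRecord, VariantRecord
from .qc import is_hotspot

NFKB_PATHWAY_GENES = ("MYD88", "CD79B", "CARD11", "TNFAIP3")
DRIVER_GENES = ("MYD88", "CD79B")  # plus CDKN2A loss

ONCOPRINT_CATEGORIES = (
    "hotspot_mutation",
    "other_mutation",
    "loss",
    "rearrangement",
    "multiple",
    "none",
)


@dataclass
class PatientProfile:
    """Merged per-patient alteration state at the primary/pre-treatment
    time point. ``cdkn2a_loss`` is None when coverage-based assessment was
    not possible; ``n_pathogenic_mutations`` is the count of retained
    variant records for the patient's primary sample."""

    patient_id: str
    mutated_genes: set[str] = field(default_factory=set)
    hotspots: set[tuple[str, str]] = field(default_factory=set)
    cdkn2a_loss: bool | None = None
    rearrangements: set[str] = field(default_factory=set)
    n_pathogenic_mutations: int = 0
    relapse_group: str = "non_relapse"  # relapse_refractory | non_relapse
    clinical: ClinicalRecord | None = None

    def __post_init__(self) -> None:
        if self.relapse_group not in ("relapse_refractory", "non_relapse"):
            raise ValueError(f"unknown relapse_group {self.relapse_group!r}")

    @property
    def double_hit(self) -> bool:
        return "MYC" in self.rearrangements and bool(
            {"BCL2", "BCL6"} & self.rearrangements
        )

    def altered_genes(self) -> set[str]:
        out = set(self.mutated_genes) | set(self.rearrangements)
        if self.cdkn2a_loss:
            out.add("CDKN2A")
        return out


def profile_from_variants(
    patient_id: str,
    retained_variants: Sequence[VariantRecord],
    cdkn2a_loss: bool | None = None,
    rearrangements: set[str] | None = None,
    relapse_group: str = "non_relapse",
    clinical: ClinicalRecord | None = None,
) -> PatientProfile:
    """Fold one sample's retained variants into a profile."""
    return PatientProfile(
        patient_id=patient_id,
        mutated_genes={v.gene for v in retained_variants},
        hotspots={(v.gene, v.protein_change) for v in retained_variants if is_hotspot(v)},
        cdkn2a_loss=cdkn2a_loss,
        rearrangements=set(rearrangements or ()),
        n_pathogenic_mutations=len(retained_variants),
        relapse_group=relapse_group,
        clinical=clinical,
    )


# ------------------------------------------------------------ frequencies


def gene_frequency_table(profiles: Sequence[PatientProfile]) -> pd.DataFrame:
    """Per-gene alteration counts over the cohort, sorted descending.

    Columns: n_mutated (point mutations/indels), n_loss, n_rearranged,
    n_any (patients with any alteration of the gene) and the matching
    fractions of the cohort size.
    """
    if not profiles:
        raise ValueError("empty profile list")
    n = len(profiles)
    genes = sorted(
        set().union(*(p.altered_genes() for p in profiles)) or set()
    )
    rows = []
    for g in genes:
        n_mut = sum(1 for p in profiles if g in p.mutated_genes)
        n_loss = sum(1 for p in profiles if g == "CDKN2A" and p.cdkn2a_loss)
        n_rearr = sum(1 for p in profiles if g in p.rearrangements)
        n_any = sum(1 for p in profiles if g in p.altered_genes())
        rows.append(
            {
                "gene": g,
                "n_mutated": n_mut,
                "n_loss": n_loss,
                "n_rearranged": n_rearr,
                "n_any": n_any,
                "fraction_mutated": n_mut / n,
                "fraction_any": n_any / n,
            }
        )
    columns = ["gene", "n_mutated", "n_loss", "n_rearranged", "n_any",
               "fraction_mutated", "fraction_any"]
    table = pd.DataFrame(rows, columns=columns).sort_values(
        ["n_any", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    return table


def pathway_frequency(
    profiles: Sequence[PatientProfile],
    genes: Sequence[str] = NFKB_PATHWAY_GENES,
) -> tuple[int, float]:
    """Patients with a mutation in any of ``genes`` (default: the NF-kB
    pathway set MYD88/CD79B/CARD11/TNFAIP3)."""
    if not profiles:
        raise ValueError("empty profile list")
    n = sum(1 for p in profiles if set(genes) & p.mutated_genes)
    return n, n / len(profiles)


def format_percent(fraction: float) -> str:
    """Render a fraction the way cohort tables print it (79% for 45/57)."""
    return f"{round(fraction * 100):.0f}%"


# --------------------------------------------------------- driver coverage


def driver_coverage(
    profiles: Sequence[PatientProfile],
) -> tuple[int, float, dict[str, bool]]:
    """Patients harbouring >= 1 main driver alteration: a MYD88 or CD79B
    mutation and/or CDKN2A loss. A missing (None) cdkn2a_loss contributes
    False to its disjunct."""
    flags = {}
    for p in profiles:
        flags[p.patient_id] = bool(
            set(DRIVER_GENES) & p.mutated_genes or p.cdkn2a_loss
        )
    n_cov = sum(flags.values())
    return n_cov, n_cov / len(profiles) if profiles else float("nan"), flags


# ------------------------------------------------------------- contingency


@dataclass
class ContingencyResult:
    table: np.ndarray  # rows: relapse_refractory, non_relapse; cols: with, without
    chi2: float | None
    p: float | None

    @property
    def undefined(self) -> bool:
        return self.p is None


def chi_square_2x2(table: np.ndarray, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (no continuity correction by
    default)."""
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def group_contingency(
    profiles: Sequence[PatientProfile],
    feature: str | Callable[[PatientProfile], bool],
    yates: bool = False,
) -> ContingencyResult:
    """2x2 comparison of a feature between relapse/refractory and
    non-relapse patients.

    ``feature`` is a gene name (any alteration of that gene counts) or a
    predicate over profiles. Returns an undefined flag (p None) when a
    margin is empty — feature absent (or universal) or a group empty.
    """
    if isinstance(feature, str):
        gene = feature
        pred = lambda p: gene in p.altered_genes()  # noqa: E731
    else:
        pred = feature
    groups = ("relapse_refractory", "non_relapse")
    table = np.zeros((2, 2), dtype=int)
    for p in profiles:
        i = groups.index(p.relapse_group)
        j = 0 if pred(p) else 1
        table[i, j] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ContingencyResult(table=table, chi2=None, p=None)
    chi2, pval = chi_square_2x2(table, yates=yates)
    return ContingencyResult(table=table, chi2=chi2, p=pval)


# --------------------------------------------------------------- oncoprint


def _cell_category(p: PatientProfile, gene: str) -> str:
    kinds = []
    if gene in p.mutated_genes:
        kinds.append(
            "hotspot_mutation" if any(g == gene for g, _ in p.hotspots) else "other_mutation"
        )
    if gene == "CDKN2A" and p.cdkn2a_loss:
        kinds.append("loss")
    if gene in p.rearrangements:
        kinds.append("rearrangement")
    if not kinds:
        return "none"
    return kinds[0] if len(kinds) == 1 else "multiple"


def oncoprint_matrix(
    profiles: Sequence[PatientProfile],
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Gene x patient categorical matrix plus marginal alteration counts.

    Genes are ordered by descending alteration frequency; cells take one
    of ONCOPRINT_CATEGORIES, with "multiple" when a gene carries more than
    one alteration type in a patient. Per-gene marginals equal the n_any
    column of gene_frequency_table.
    """
    if not profiles:
        raise ValueError("empty profile list")
    freq = gene_frequency_table(profiles)
    genes = list(freq["gene"])
    patients = [p.patient_id for p in profiles]
    matrix = pd.DataFrame("none", index=genes, columns=patients)
    for p in profiles:
        for g in genes:
            matrix.loc[g, p.patient_id] = _cell_category(p, g)
    gene_marginals = (matrix != "none").sum(axis=1)
    patient_marginals = (matrix != "none").sum(axis=0)
    return matrix, gene_marginals, patient_marginals


# ------------------------------------------------------- mutational burden


def burden_dichotomy(profiles: Sequence[PatientProfile]) -> tuple[float, dict[str, bool]]:
    """Median pathogenic-mutation count and per-patient high-burden flags
    (count strictly above the cohort median). The threshold is computed
    from the data at hand, never hard-coded."""
    if not profiles:
        raise ValueError("empty profile list")
    counts = np.array([p.n_pathogenic_mutations for p in profiles], dtype=float)
    med = float(np.median(counts))
    return med, {p.patient_id: p.n_pathogenic_mutations > med for p in profiles}


# --------------------------------------------------- classifier feature export


def lymphgen_feature_export(profiles: Sequence[PatientProfile]) -> pd.DataFrame:
    """Export stub of the per-sample feature table an external DLBCL
    genetic-subtype classifier expects (mutation flags plus BCL2/BCL6
    rearrangement status); classification itself is an external web
    service and out of scope."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "sample_id": p.patient_id,
                "mutated_genes": ";".join(sorted(p.mutated_genes)),
                "bcl2_rearranged": "BCL2" in p.rearrangements,
                "bcl6_rearranged": "BCL6" in p.rearrangements,
                "myc_rearranged": "MYC" in p.rearrangements,
            }
        )
    return pd.DataFrame(rows)
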