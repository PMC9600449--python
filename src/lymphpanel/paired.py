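"""Stability of the molecular profile between primary and relapse biopsies.

Alterations are matched by canonical key — exact site for small variants
(gene, chrom, pos, ref, alt), gene-level for copy-number loss and
rearrangements — and partitioned into stable (both time points), lost
(primary only) and gained (relapse only). Genes that lose one variant
and gain another of the same mutation type are additionally flagged
same_gene_different_site: the pattern expected from ongoing somatic
hypermutation rather than clonal replacement. Driver stability
(MYD88/CD79B hotspot mutations, CDKN2A loss) is tracked separately;
hotspot genes are assessed at hotspot level when a hotspot was seen at
either time point, else at gene level.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cnv import CnvCall
from .models import VariantRecord
from .qc import is_hotspot

DRIVERS = ("MYD88-mut", "CD79B-mut", "CDKN2A-loss")

AlterationKey = tuple


def variant_key(v: VariantRecord) -> AlterationKey:
    """Exact-site identity for small variants."""
    return (v.gene, v.chrom, v.pos, v.ref, v.alt)


def loss_key(gene: str) -> AlterationKey:
    return (gene, "loss")


def rearrangement_key(gene: str) -> AlterationKey:
    return (gene, "rearrangement")


def alteration_key(obj) -> AlterationKey:
    """Canonical key of any alteration record; deterministic and injective
    within its type (a CDKN2A loss never collides with a CDKN2A SNV)."""
    if isinstance(obj, VariantRecord):
        return variant_key(obj)
    if isinstance(obj, CnvCall):
        return loss_key(obj.gene)
    raise TypeError(f"cannot key {type(obj).__name__}; use loss_key/rearrangement_key")


@dataclass
class SampleAlterations:
    """One biopsy's alteration state: retained variants plus gene-level
    CNV-loss and rearrangement flags."""

    sample_id: str
    variants: list[VariantRecord] = field(default_factory=list)
    losses: set[str] = field(default_factory=set)  # genes with CNV loss
    rearrangements: set[str] = field(default_factory=set)

    def keys(self) -> set[AlterationKey]:
        out = {variant_key(v) for v in self.variants}
        out |= {loss_key(g) for g in self.losses}
        out |= {rearrangement_key(g) for g in self.rearrangements}
        return out

    def mutation_types(self) -> dict[AlterationKey, str]:
        return {variant_key(v): v.mutation_type for v in self.variants}

    def hotspot_genes(self) -> set[str]:
        return {v.gene for v in self.variants if is_hotspot(v)}

    def mutated_genes(self) -> set[str]:
        return {v.gene for v in self.variants}


@dataclass
class PairedComparison:
    patient_id: str
    stable: set[AlterationKey]
    lost: set[AlterationKey]
    gained: set[AlterationKey]
    same_gene_different_site: set[str]
    driver_state: dict[str, str]  # driver -> stable_present|stable_absent|gained|lost
    time_between_biopsies_months: float | None = None

    def __post_init__(self) -> None:
        # partition invariant: asserted, not assumed
        if self.stable & self.lost or self.stable & self.gained or self.lost & self.gained:
            raise ValueError(f"{self.patient_id}: stable/lost/gained not disjoint")

    @property
    def any_driver_stable(self) -> bool:
        return any(s == "stable_present" for s in self.driver_state.values())

    @property
    def all_keys(self) -> set[AlterationKey]:
        return self.stable | self.lost | self.gained


def _presence_state(in_primary: bool, in_relapse: bool) -> str:
    if in_primary and in_relapse:
        return "stable_present"
    if in_primary:
        return "lost"
    if in_relapse:
        return "gained"
    return "stable_absent"


def _driver_states(primary: SampleAlterations, relapse: SampleAlterations) -> dict[str, str]:
    states = {}
    for gene in ("MYD88", "CD79B"):
        hs_p = gene in primary.hotspot_genes()
        hs_r = gene in relapse.hotspot_genes()
        if hs_p or hs_r:
            states[f"{gene}-mut"] = _presence_state(hs_p, hs_r)
        else:
            states[f"{gene}-mut"] = _presence_state(
                gene in primary.mutated_genes(), gene in relapse.mutated_genes()
            )
    states["CDKN2A-loss"] = _presence_state(
        "CDKN2A" in primary.losses, "CDKN2A" in relapse.losses
    )
    return states


def compare_pair(
    patient_id: str,
    primary: SampleAlterations,
    relapse: SampleAlterations,
    time_between_biopsies_months: float | None = None,
    expected_patient: Mapping[str, str] | None = None,
) -> PairedComparison:
    """Partition the union of both biopsies' alteration keys.

    ``expected_patient`` optionally maps sample_id -> patient_id; when
    given, both samples must resolve to ``patient_id``.
    """
    if expected_patient is not None:
        for s in (primary, relapse):
            if expected_patient.get(s.sample_id) != patient_id:
                raise ValueError(
                    f"sample {s.sample_id!r} does not belong to patient {patient_id!r}"
                )
    pk, rk = primary.keys(), relapse.keys()
    stable = pk & rk
    lost = pk - rk
    gained = rk - pk

    # SHM fingerprint: same gene, same mutation type, different site
    ptypes, rtypes = primary.mutation_types(), relapse.mutation_types()
    flagged = set()
    for lk in lost:
        if lk not in ptypes:
            continue  # loss/rearrangement keys have no mutation type
        for gk in gained:
            if gk in rtypes and gk[0] == lk[0] and rtypes[gk] == ptypes[lk]:
                flagged.add(lk[0])

    return PairedComparison(
        patient_id=patient_id,
        stable=stable,
        lost=lost,
        gained=gained,
        same_gene_different_site=flagged,
        driver_state=_driver_states(primary, relapse),
        time_between_biopsies_months=time_between_biopsies_months,
    )


def is_driver_key(key: AlterationKey, hotspot_positions: set[AlterationKey]) -> bool:
    """Driver keys: CDKN2A loss plus MYD88/CD79B hotspot variant keys."""
    if key == loss_key("CDKN2A"):
        return True
    return key in hotspot_positions


def collect_hotspot_keys(samples: Iterable[SampleAlterations]) -> set[AlterationKey]:
    out = set()
    for s in samples:
        out |= {variant_key(v) for v in s.variants if is_hotspot(v)}
    return out


@dataclass
class PairedCohortSummary:
    n_patients: int
    n_stable: int
    n_lost: int
    n_gained: int
    per_gene: pd.DataFrame  # gene, n_lost, n_gained, total_discrepant
    n_patients_any_driver_stable: int
    driver_filter: str

    @property
    def n_total(self) -> int:
        return self.n_stable + self.n_lost + self.n_gained

    @property
    def fractions(self) -> tuple[float, float, float]:
        t = self.n_total
        if t == 0:
            return (float("nan"),) * 3
        return (self.n_stable / t, self.n_lost / t, self.n_gained / t)


def cohort_paired_summary(
    comparisons: Sequence[PairedComparison],
    driver_filter: str = "all",
    hotspot_keys: set[AlterationKey] | None = None,
) -> PairedCohortSummary:
    """Pool stable/lost/gained tallies over a paired cohort.

    ``driver_filter`` selects which alteration keys enter the tallies:
    "all", "drivers" (CDKN2A loss + hotspot variant keys) or
    "non_drivers" (everything else). Keys alone cannot identify hotspots
    (they carry no protein change), so callers filtering by driver must
    pass the hotspot variant keys explicitly — ``collect_hotspot_keys``
    gathers them from the underlying SampleAlterations.
    """
    if not comparisons:
        raise ValueError("empty comparison list")
    if driver_filter not in ("all", "drivers", "non_drivers"):
        raise ValueError(f"unknown driver_filter {driver_filter!r}")
    hotspot_keys = hotspot_keys or set()

    def selected(key: AlterationKey) -> bool:
        if driver_filter == "all":
            return True
        d = is_driver_key(key, hotspot_keys)
        return d if driver_filter == "drivers" else not d

    n_stable = n_lost = n_gained = 0
    lost_c: Counter = Counter()
    gained_c: Counter = Counter()
    n_any_stable = 0
    for c in comparisons:
        n_stable += sum(1 for k in c.stable if selected(k))
        for k in c.lost:
            if selected(k):
                n_lost += 1
                lost_c[k[0]] += 1
        for k in c.gained:
            if selected(k):
                n_gained += 1
                gained_c[k[0]] += 1
        if c.any_driver_stable:
            n_any_stable += 1

    genes = sorted(set(lost_c) | set(gained_c))
    per_gene = pd.DataFrame(
        {
            "gene": genes,
            "n_lost": [lost_c[g] for g in genes],
            "n_gained": [gained_c[g] for g in genes],
        }
    )
    per_gene["total_discrepant"] = per_gene["n_lost"] + per_gene["n_gained"]
    per_gene = per_gene.sort_values(
        ["total_discrepant", "gene"], ascending=[False, True]
    ).reset_index(drop=True)

    return PairedCohortSummary(
        n_patients=len(comparisons),
        n_stable=n_stable,
        n_lost=n_lost,
        n_gained=n_gained,
        per_gene=per_gene,
        n_patients_any_driver_stable=n_any_stable,
        driver_filter=driver_filter,
    )
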