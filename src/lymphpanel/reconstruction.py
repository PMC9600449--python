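"""Synthetic reconstruction of the 57-patient study cohort.

The study's per-patient alteration data exist only as raw sequencing
reads and figure images; what is printed are cohort marginals. This
module builds a SYNTHETIC cohort of 57 patient profiles whose marginal
counts reproduce those printed numbers — MYD88 mutated 45 (L265P in 39),
CD79B 31 (both 24), CARD11 6, TNFAIP3 5, PIM1 21, TBL1XR1 14, KMT2D 13,
BTG1 11, BTG2 9, MEF2B 9, EP300 7, HIST1H1E 4, CDKN2A loss 36, MYC
rearranged 14 (one BCL6 double hit), driver coverage 54, median 6
pathogenic mutations (range 0-26), 39 relapse/refractory vs 18
non-relapse with MYC 14 vs 2, TBL1XR1 12 vs 2, KMT2D 11 vs 2 — so the
summarizer's arithmetic can be regression-tested against the printed
percentages. The patient-level assignment is an invention constrained by
the marginals, not real data; note the printed per-gene counts are
mutually inconsistent with the printed NF-kB pathway union (45+31-24=52,
not 48), so only the per-gene marginals are honoured.
"""

from __future__ import annotations

import numpy as np

from .cohort import PatientProfile
from .models import ClinicalRecord

N_PATIENTS = 57

# idx ranges are deterministic; patients are LT_01..LT_57 (idx 0..56).
_GENE_ASSIGNMENTS: dict[str, range | list[int]] = {
    "MYD88": range(0, 45),                      # 45/57 = 79%
    "CD79B": [*range(0, 24), *range(45, 52)],   # 31/57 = 54%; both = 24
    "CARD11": range(10, 16),                    # 6
    "TNFAIP3": range(30, 35),                   # 5
    "PIM1": range(5, 26),                       # 21
    "TBL1XR1": [*range(2, 14), 42, 43],         # 14 = 12 relapse + 2 non
    "KMT2D": [*range(14, 25), 44, 45],          # 13 = 11 relapse + 2 non
    "BTG1": range(6, 17),                       # 11
    "BTG2": range(17, 26),                      # 9
    "MEF2B": range(18, 27),                     # 9
    "EP300": range(27, 34),                     # 7
    "HIST1H1E": range(0, 4),                    # 4
    "MYC": [20, 21],                            # 2 point-mutated
}

_MYD88_L265P = range(0, 39)                     # hotspot in 39 of the 45
_CD79B_Y196 = [*range(0, 20), *range(45, 50)]   # hotspot subset (count unprinted)
_CDKN2A_LOSS = [*range(0, 34), 52, 53]          # 36; covers 2 driver-negative patients
_MYC_REARRANGED = [*range(0, 12), 40, 41]       # 14 = 12 relapse + 2 non-relapse
_BCL6_REARRANGED = [0]                          # the single double hit
_RELAPSE_GROUP = range(0, 39)                   # 39 relapse/refractory, 18 non


# gene assignments cluster at low patient indices; outcomes are assigned
# through a fixed permutation so clinical status is not index-correlated
_OUTCOME_ORDER = np.random.default_rng(2020).permutation(N_PATIENTS)


def _clinical(i: int, pid: str, relapse: bool, myc_rearranged: bool) -> ClinicalRecord:
    # 21 lymphoma deaths, 16 other-cause, 20 alive — deterministic spread
    k = int(_OUTCOME_ORDER[i])
    if k < 21:
        cause, fu = "lymphoma", 3.0 + 2.5 * k
        os_e = dss_e = True
    elif k < 37:
        cause, fu = "other", 8.0 + 4.0 * (k - 21)
        os_e, dss_e = True, False
    else:
        cause, fu = "alive", 10.0 + 7.0 * (k - 37)
        os_e = dss_e = False
    tte = round(0.6 * fu, 1) if relapse else fu
    pfs_e = relapse or cause == "lymphoma"
    return ClinicalRecord(
        patient_id=pid,
        treatment=("local", "systemic", "combined")[i % 3],
        response="refractory_progressive" if i in (15, 41) else "CR",
        relapse_flag=relapse,
        time_to_event_months=tte,
        follow_up_months=fu,
        os_event=os_e,
        dss_event=dss_e,
        pfs_event=pfs_e,
        death_cause=cause,
        myc_rearranged=myc_rearranged,
    )


def _pathogenic_counts(gene_counts: list[int]) -> list[int]:
    """Deterministic per-patient variant counts with median 6, min 0,
    max 26, each >= the patient's mutated-gene count."""
    counts = list(gene_counts)
    # raise the upper half until the cohort median reaches 6
    while float(np.median(counts)) < 6.0:
        med = float(np.median(counts))
        counts = [c + 1 if c >= med and c > 0 else c for c in counts]
    counts[0] = 26  # the single hypermutated outlier case
    assert float(np.median(counts)) == 6.0
    assert min(counts) == 0 and max(counts) == 26
    return counts


def synthetic_reconstruction_cohort() -> list[PatientProfile]:
    """Build the 57 synthetic profiles (see module docstring)."""
    assigned: dict[int, set[str]] = {i: set() for i in range(N_PATIENTS)}
    for gene, idxs in _GENE_ASSIGNMENTS.items():
        for i in idxs:
            assigned[i].add(gene)

    gene_counts = [len(assigned[i]) for i in range(N_PATIENTS)]
    n_path = _pathogenic_counts(gene_counts)

    profiles = []
    for i in range(N_PATIENTS):
        pid = f"LT_{i + 1:02d}"
        hotspots = set()
        if i in _MYD88_L265P:
            hotspots.add(("MYD88", "L265P"))
        if i in _CD79B_Y196:
            hotspots.add(("CD79B", "Y196S"))
        rearr = set()
        if i in _MYC_REARRANGED:
            rearr.add("MYC")
        if i in _BCL6_REARRANGED:
            rearr.add("BCL6")
        relapse = i in _RELAPSE_GROUP
        profiles.append(
            PatientProfile(
                patient_id=pid,
                mutated_genes=set(assigned[i]),
                hotspots=hotspots,
                cdkn2a_loss=i in _CDKN2A_LOSS,
                rearrangements=rearr,
                n_pathogenic_mutations=n_path[i],
                relapse_group="relapse_refractory" if relapse else "non_relapse",
                clinical=_clinical(i, pid, relapse, "MYC" in rearr),
            )
        )
    return profiles
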