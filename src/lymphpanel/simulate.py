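"""Synthetic cohorts with the statistical structure the pipeline assumes.

Emulates the inputs of a 52-gene B-cell-lymphoma amplicon panel run on
FFPE skin biopsies: per-amplicon read counts with shared systematic
efficiency factors and negative-binomial noise, purity-diluted CDKN2A
deletions, hotspot-driven variant tables with FFPE transition artefacts,
paired primary/relapse samples with clone retention and SHM-driven gains,
and exponential survival times with covariate hazards.

All draws are seeded; the same seed and config give byte-identical output.
Per-sample substreams are derived from a CRC32 of the sample id so the
output does not depend on iteration order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import Amplicon, AmpliconPanel, ClinicalRecord, CoverageMatrix, VariantRecord

#: The 52 genes of the panel.
PANEL_GENES = [
    "MYD88", "CD79B", "CD79A", "CARD11", "TNFAIP3", "PIM1", "TBL1XR1",
    "KMT2D", "BTG1", "BTG2", "MEF2B", "EP300", "CDKN2A", "MYC", "HIST1H1E",
    "ETV6", "CD70", "BCL2", "BCL6", "IRF4", "PRDM1", "STAT3", "XPO1",
    "NOTCH1", "NOTCH2", "TP53", "B2M", "TNFRSF14", "SOCS1", "SGK1", "GNA13",
    "EZH2", "CREBBP", "ARID1A", "FOXO1", "BRAF", "BTK", "PLCG2", "NFKBIE",
    "DUSP2", "ZFP36L1", "ITPKB", "BCL10", "CXCR4", "KLHL6", "POU2F2",
    "IKZF3", "TMEM30A", "S1PR2", "CCND3", "STAT6", "TET2",
]

assert len(PANEL_GENES) == 52

#: Genes that are recurrent targets of aberrant somatic hypermutation and
#: therefore gain point mutations between biopsies.
SHM_TARGET_GENES = ("PIM1", "MYC", "BTG1", "CDKN2A")

MYD88_HOTSPOT = dict(gene="MYD88", chrom="chr3", pos=38182641, ref="T", alt="C",
                     protein_change="L265P")
CD79B_HOTSPOT_POS = dict(gene="CD79B", chrom="chr17", pos=62006799, ref="T")
CD79B_Y196_ALTS = [("C", "Y196S"), ("G", "Y196H"), ("A", "Y196N")]

# Anchor coordinates for the three genes with fixed biology; the rest of
# the panel is laid out deterministically.
_GENE_ANCHORS = {"MYD88": ("chr3", 38182000), "CD79B": ("chr17", 62006500),
                 "CDKN2A": ("chr9", 21967000)}


def default_gene_mutation_probs() -> dict[str, float]:
    """Per-gene probabilities of a non-hotspot mutation, calibrated so the
    marginal mutated-gene frequencies match the cohort frequencies
    (MYD88 79%, CD79B 54%, PIM1 37%, ...) given the hotspot marginals."""
    probs = {g: 0.03 for g in PANEL_GENES}
    probs.update(
        {
            # marginal 0.79 = 1 - (1 - 0.684) * (1 - q)
            "MYD88": 1.0 - (1.0 - 0.79) / (1.0 - 0.684),
            # marginal 0.54 = 1 - (1 - 0.42) * (1 - q)
            "CD79B": 1.0 - (1.0 - 0.54) / (1.0 - 0.42),
            "CARD11": 6 / 57,
            "TNFAIP3": 5 / 57,
            "PIM1": 21 / 57,
            "TBL1XR1": 14 / 57,
            "KMT2D": 13 / 57,
            "BTG1": 11 / 57,
            "BTG2": 9 / 57,
            "MEF2B": 9 / 57,
            "EP300": 7 / 57,
            "HIST1H1E": 4 / 57,
            "MYC": 0.12,
            "ETV6": 0.05,
            "CD70": 0.05,
            "CDKN2A": 0.08,
        }
    )
    return probs


@dataclass
class SimulationConfig:
    """Generator parameters; defaults encode the observed cohort conditions.

    ``hotspot_probs`` are marginal per-patient probabilities of carrying
    the MYD88 L265P and a CD79B Y196 substitution; ``gene_mutation_probs``
    govern additional non-hotspot mutations (so marginal gene frequencies
    are 1 - (1-p_hot)(1-p_gene) for the two hotspot genes).
    ``depth_dispersion`` is the negative-binomial size parameter r
    (var = m + m^2/r); 200 at depth 1000 gives ~8% per-amplicon CV, the
    residual noise of a well-behaved amplicon assay after normalization.
    ``retention_prob`` is the chance a non-driver primary variant is still
    seen at relapse; driver hotspots and CDKN2A loss persist with
    ``driver_persistence`` (1 by default: genetic stability of the main
    drivers is the generator's null hypothesis).
    ``background_variant_rate`` is the Poisson mean of benign class-1/2
    calls per sample (germline polymorphisms the raw caller reports);
    they are removed by the class filter but stabilize the sample-level
    Ts:Tv statistic the way real raw call sets do.
    """

    seed: int
    n_patients: int = 57
    n_paired: int = 16
    n_normals: int = 18
    gene_mutation_probs: dict[str, float] = field(default_factory=default_gene_mutation_probs)
    hotspot_probs: tuple[float, float] = (39 / 57, 0.42)
    cdkn2a_loss_prob: float = 36 / 57
    tumor_purity_range: tuple[float, float] = (0.4, 0.9)
    depth_mean: float = 1000.0
    depth_dispersion: float = 200.0
    amplicon_efficiency_sd: float = 0.2
    ffpe_transition_rate: float = 2.0
    background_variant_rate: float = 12.0
    retention_prob: float = 0.6
    driver_persistence: float = 1.0
    cdkn2a_gain_prob: float = 2 / 16
    shm_gain_rate: float = 0.4
    hazard_log_hr: dict[str, float] = field(default_factory=dict)
    censor_rate: float = 0.01
    baseline_hazard: float = math.log(2) / 44.0

    def __post_init__(self) -> None:
        probs = [
            *self.gene_mutation_probs.values(),
            *self.hotspot_probs,
            self.cdkn2a_loss_prob,
            self.retention_prob,
            self.driver_persistence,
            self.cdkn2a_gain_prob,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be > 0")
        if self.censor_rate < 0 or self.baseline_hazard <= 0:
            raise ValueError("rates must be positive")
        lo, hi = self.tumor_purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("tumor_purity_range must satisfy 0 < lo <= hi <= 1")


def _rng(config: SimulationConfig, stream: int, key: str | None = None) -> np.random.Generator:
    seq = [int(config.seed) % (2**31), stream]
    if key is not None:
        seq.append(zlib.crc32(key.encode()))
    return np.random.default_rng(seq)


# ------------------------------------------------------------------ panel


def build_default_panel(n_cdkn2a_amplicons: int = 8, amplicons_per_gene: int = 4) -> AmpliconPanel:
    """Deterministic panel layout: every gene tiled by ``amplicons_per_gene``
    150-bp amplicons (CDKN2A by ``n_cdkn2a_amplicons``)."""
    amplicons = []
    for i, gene in enumerate(PANEL_GENES):
        chrom, start = _GENE_ANCHORS.get(gene, (f"chr{(i % 22) + 1}", 1_000_000 + 120_000 * i))
        n_amp = n_cdkn2a_amplicons if gene == "CDKN2A" else amplicons_per_gene
        for k in range(n_amp):
            s = start + 250 * k
            amplicons.append(Amplicon(f"{gene}_amp{k + 1:02d}", gene, chrom, s, s + 150))
    return AmpliconPanel(amplicons)


def _gene_region(panel: AmpliconPanel, gene: str) -> tuple[str, int, int]:
    amps = panel.gene_amplicons(gene)
    return amps[0].chrom, amps[0].start, amps[-1].end


# --------------------------------------------------------------- coverage


def simulate_coverage(
    config: SimulationConfig,
    panel: AmpliconPanel,
    truth: pd.DataFrame,
    gene: str = "CDKN2A",
) -> tuple[CoverageMatrix, pd.DataFrame]:
    """Draw raw amplicon read counts for the samples described in ``truth``.

    ``truth`` needs columns sample_id, loss (none|monoallelic|biallelic)
    and purity. Counts are negative-binomial around
    depth_mean x efficiency x dosage, where the per-amplicon efficiency is
    log-normal (sd ``amplicon_efficiency_sd`` on the natural-log scale) and
    shared across samples — the same config always yields the same
    systematic amplicon profile, so normals and tumors generated from one
    config share it. Dosage on the target gene's amplicons is
    1 - purity/2 (monoallelic loss) or 1 - purity (biallelic), 1 elsewhere.
    """
    required = {"sample_id", "loss", "purity"}
    if not required <= set(truth.columns):
        raise ValueError(f"truth needs columns {sorted(required)}")
    bad = ~truth["loss"].isin(["none", "monoallelic", "biallelic"])
    if bad.any():
        raise ValueError(f"unknown loss labels: {truth.loc[bad, 'loss'].unique()}")
    purity = truth["purity"].to_numpy(dtype=float)
    if ((purity <= 0) | (purity > 1)).any():
        raise ValueError("purity must be in (0, 1]")
    if gene not in panel.gene_index:
        raise ValueError(f"panel lacks gene {gene!r}")

    n_amp = len(panel)
    eff = np.exp(_rng(config, 11).normal(0.0, config.amplicon_efficiency_sd, size=n_amp))
    target = np.array([a.gene == gene for a in panel.amplicons])
    r = config.depth_dispersion

    cols = {}
    for row in truth.itertuples(index=False):
        dosage = np.ones(n_amp)
        if row.loss == "monoallelic":
            dosage[target] = 1.0 - row.purity / 2.0
        elif row.loss == "biallelic":
            dosage[target] = 1.0 - row.purity
        mu = config.depth_mean * eff * dosage
        rng = _rng(config, 12, str(row.sample_id))
        p = r / (r + mu)
        cols[str(row.sample_id)] = rng.negative_binomial(r, p)
    df = pd.DataFrame(cols, index=panel.amplicon_ids)
    return CoverageMatrix(df), truth.copy()


def simulate_normals(config: SimulationConfig, panel: AmpliconPanel) -> CoverageMatrix:
    """Coverage for the panel of normals (non-neoplastic libraries)."""
    truth = pd.DataFrame(
        {
            "sample_id": [f"N{i + 1:02d}" for i in range(config.n_normals)],
            "loss": "none",
            "purity": 1.0,
        }
    )
    cov, _ = simulate_coverage(config, panel, truth)
    return cov


# --------------------------------------------------------------- variants

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "C": "AG", "G": "CT", "T": "AG"}


def _draw_substitution(rng: np.random.Generator, p_transition: float = 2 / 3) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    if rng.random() < p_transition:
        return ref, _TRANSITION[ref]
    return ref, _TRANSVERSIONS[ref][rng.integers(2)]


def _somatic_record(
    rng: np.random.Generator,
    config: SimulationConfig,
    sample_id: str,
    gene: str,
    panel: AmpliconPanel,
) -> VariantRecord:
    chrom, start, end = _gene_region(panel, gene)
    pos = int(rng.integers(start + 1, end + 1))  # 1-based
    ref, alt = _draw_substitution(rng)
    vaf = float(np.clip(rng.beta(4, 6), 0.01, 0.99))
    depth = _nb_depth(rng, config)
    vclass = int(rng.choice([3, 4, 5], p=[0.25, 0.35, 0.40]))
    cadd = float(np.round(rng.normal(25, 8), 1)) if vclass >= 3 else None
    ndam = int(rng.binomial(4, 0.5))
    return VariantRecord(
        sample_id=sample_id, gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
        vaf=round(vaf, 4), depth=depth, variant_class=vclass,
        cadd_phred=max(cadd, 0.1) if cadd is not None else None,
        n_damaging_predictions=ndam,
        mutation_type=str(rng.choice(
            ["nonsynonymous", "nonsense", "frameshift", "splice"],
            p=[0.7, 0.12, 0.12, 0.06],
        )),
    )


def _nb_depth(rng: np.random.Generator, config: SimulationConfig) -> int:
    r = config.depth_dispersion
    return int(rng.negative_binomial(r, r / (r + config.depth_mean)))


def _artefact_record(
    rng: np.random.Generator,
    config: SimulationConfig,
    sample_id: str,
    panel: AmpliconPanel,
) -> VariantRecord:
    # FFPE cytosine deamination: exclusively C>T / G>A transitions at low VAF
    gene = str(rng.choice(PANEL_GENES))
    chrom, start, end = _gene_region(panel, gene)
    pos = int(rng.integers(start + 1, end + 1))
    ref = "C" if rng.random() < 0.5 else "G"
    alt = _TRANSITION[ref]
    vaf = float(rng.uniform(0.02, 0.0999))
    return VariantRecord(
        sample_id=sample_id, gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
        vaf=round(vaf, 4), depth=_nb_depth(rng, config),
        variant_class=int(rng.choice([1, 2, 3], p=[0.3, 0.4, 0.3])),
        cadd_phred=float(np.round(rng.uniform(0.5, 15), 1)),
        n_damaging_predictions=int(rng.integers(0, 2)),
        mutation_type=str(rng.choice(["synonymous", "nonsynonymous"])),
    )


def _background_record(
    rng: np.random.Generator,
    config: SimulationConfig,
    sample_id: str,
    panel: AmpliconPanel,
) -> VariantRecord:
    # benign germline polymorphism: heterozygous VAF, class 1/2
    gene = str(rng.choice(PANEL_GENES))
    chrom, start, end = _gene_region(panel, gene)
    pos = int(rng.integers(start + 1, end + 1))
    ref, alt = _draw_substitution(rng)
    vaf = float(np.clip(rng.normal(0.5, 0.05), 0.3, 0.7))
    return VariantRecord(
        sample_id=sample_id, gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
        vaf=round(vaf, 4), depth=_nb_depth(rng, config),
        variant_class=int(rng.integers(1, 3)),
        cadd_phred=float(np.round(rng.uniform(0.1, 10), 1)),
        n_damaging_predictions=0,
        mutation_type=str(rng.choice(["synonymous", "nonsynonymous"])),
    )


def simulate_variants(
    config: SimulationConfig,
    panel: AmpliconPanel | None = None,
    patient_ids: Sequence[str] | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Per-patient raw variant calls: true somatic mutations, benign
    background polymorphisms, and FFPE artefacts.

    Each gene mutates independently with its configured probability; the
    two hotspots are emitted with their marginal probabilities and stated
    protein changes. Artefact counts are Poisson(ffpe_transition_rate),
    background counts Poisson(background_variant_rate). Returns the
    records plus a truth table flagging hotspot/artefact/background rows.
    """
    panel = panel or build_default_panel()
    unknown = set(config.gene_mutation_probs) - set(panel.gene_index)
    if unknown:
        raise ValueError(f"gene_mutation_probs keys not in panel: {sorted(unknown)}")
    if patient_ids is None:
        patient_ids = [f"LT_{i + 1:02d}" for i in range(config.n_patients)]

    p_myd88, p_cd79b = config.hotspot_probs
    records: list[VariantRecord] = []
    truth_rows = []
    for pid in patient_ids:
        rng = _rng(config, 21, pid)
        sample_records: list[VariantRecord] = []
        if rng.random() < p_myd88:
            sample_records.append(
                VariantRecord(
                    sample_id=pid, vaf=round(float(np.clip(rng.beta(4, 6), 0.01, 0.99)), 4),
                    depth=_nb_depth(rng, config), variant_class=5,
                    mutation_type="nonsynonymous", **MYD88_HOTSPOT,
                )
            )
        if rng.random() < p_cd79b:
            alt, pchange = CD79B_Y196_ALTS[rng.integers(len(CD79B_Y196_ALTS))]
            sample_records.append(
                VariantRecord(
                    sample_id=pid, alt=alt, protein_change=pchange,
                    vaf=round(float(np.clip(rng.beta(4, 6), 0.01, 0.99)), 4),
                    depth=_nb_depth(rng, config), variant_class=5,
                    mutation_type="nonsynonymous", **CD79B_HOTSPOT_POS,
                )
            )
        for gene in PANEL_GENES:
            p = config.gene_mutation_probs.get(gene, 0.0)
            if rng.random() < p:
                sample_records.append(_somatic_record(rng, config, pid, gene, panel))
        n_art = rng.poisson(config.ffpe_transition_rate)
        artefacts = [_artefact_record(rng, config, pid, panel) for _ in range(n_art)]
        n_bg = rng.poisson(config.background_variant_rate)
        background = [_background_record(rng, config, pid, panel) for _ in range(n_bg)]

        def truth_row(v, is_hotspot=False, is_artefact=False, is_background=False):
            return dict(sample_id=pid, gene=v.gene, chrom=v.chrom, pos=v.pos,
                        ref=v.ref, alt=v.alt, vaf=v.vaf, is_hotspot=is_hotspot,
                        is_artefact=is_artefact, is_background=is_background)

        for v in sample_records:
            truth_rows.append(truth_row(v, is_hotspot=bool(v.protein_change)))
        for v in artefacts:
            truth_rows.append(truth_row(v, is_artefact=True))
        for v in background:
            truth_rows.append(truth_row(v, is_background=True))
        records.extend(sample_records)
        records.extend(artefacts)
        records.extend(background)
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "gene", "chrom", "pos", "ref", "alt", "vaf",
                 "is_hotspot", "is_artefact", "is_background"],
    )
    return records, truth


def is_driver_hotspot(v: VariantRecord) -> bool:
    """MYD88 L265P or any CD79B Y196 substitution."""
    return (v.gene == "MYD88" and v.protein_change == "L265P") or (
        v.gene == "CD79B" and v.protein_change.startswith("Y196")
    )


# ----------------------------------------------------------------- paired


def simulate_paired(
    config: SimulationConfig,
    primary_records: Sequence[VariantRecord],
    primary_loss: Mapping[str, bool] | None = None,
    panel: AmpliconPanel | None = None,
    relapse_suffix: str = "-R",
) -> tuple[list[VariantRecord], dict[str, bool]]:
    """Evolve primary variant sets into relapse sets.

    Driver alterations (MYD88/CD79B hotspots, CDKN2A loss) persist with
    ``driver_persistence`` (1 by default); every other variant persists
    with ``retention_prob``; each SHM-target gene gains
    Poisson(shm_gain_rate) new point variants; CDKN2A loss can be acquired
    with ``cdkn2a_gain_prob``.
    """
    panel = panel or build_default_panel()
    primary_loss = dict(primary_loss or {})
    by_patient: dict[str, list[VariantRecord]] = {}
    for v in primary_records:
        by_patient.setdefault(v.sample_id, []).append(v)
    patients = sorted(set(by_patient) | set(primary_loss))

    relapse: list[VariantRecord] = []
    relapse_loss: dict[str, bool] = {}
    for pid in patients:
        rng = _rng(config, 31, pid)
        rid = pid + relapse_suffix
        for v in by_patient.get(pid, []):
            keep_p = config.driver_persistence if is_driver_hotspot(v) else config.retention_prob
            if rng.random() < keep_p:
                relapse.append(
                    VariantRecord(
                        sample_id=rid, gene=v.gene, chrom=v.chrom, pos=v.pos,
                        ref=v.ref, alt=v.alt, vaf=v.vaf, depth=v.depth,
                        variant_class=v.variant_class, protein_change=v.protein_change,
                        cadd_phred=v.cadd_phred,
                        n_damaging_predictions=v.n_damaging_predictions,
                        mutation_type=v.mutation_type,
                    )
                )
        for gene in SHM_TARGET_GENES:
            for _ in range(rng.poisson(config.shm_gain_rate)):
                relapse.append(_somatic_record(rng, config, rid, gene, panel))
        if pid in primary_loss:
            if primary_loss[pid]:
                relapse_loss[rid] = rng.random() < config.driver_persistence
            else:
                relapse_loss[rid] = rng.random() < config.cdkn2a_gain_prob
    return relapse, relapse_loss


# --------------------------------------------------------------- survival


def simulate_survival(
    config: SimulationConfig, covariates: pd.DataFrame
) -> list[ClinicalRecord]:
    """Exponential event times with proportional covariate hazards.

    Event rate per patient is baseline_hazard * exp(sum beta*x) with betas
    from ``hazard_log_hr`` (keys must be covariate columns); independent
    exponential censoring at rate ``censor_rate`` (0 = no censoring).
    Administrative 5-year censoring is the survival module's job, not the
    generator's.
    """
    missing = set(config.hazard_log_hr) - set(covariates.columns)
    if missing:
        raise ValueError(f"hazard_log_hr keys not in covariates: {sorted(missing)}")
    records = []
    for pid, row in covariates.iterrows():
        rng = _rng(config, 41, str(pid))
        lp = sum(beta * float(row[cov]) for cov, beta in config.hazard_log_hr.items())
        rate = config.baseline_hazard * math.exp(lp)
        t_event = rng.exponential(1.0 / rate)
        t_censor = rng.exponential(1.0 / config.censor_rate) if config.censor_rate > 0 else math.inf
        t = min(t_event, t_censor)
        event = t_event <= t_censor
        records.append(
            ClinicalRecord(
                patient_id=str(pid), treatment="systemic", response="CR",
                relapse_flag=event, time_to_event_months=round(t, 3),
                follow_up_months=round(t, 3), os_event=event, dss_event=event,
                pfs_event=event, death_cause="lymphoma" if event else "alive",
            )
        )
    return records


# ------------------------------------------------------------ full study


@dataclass
class StudyData:
    """One simulated study: coverage, variants, paired relapses, clinical."""

    panel: AmpliconPanel
    normals: CoverageMatrix
    tumors: CoverageMatrix
    loss_truth: pd.DataFrame      # sample_id, loss, purity
    variants: list[VariantRecord]
    variant_truth: pd.DataFrame
    clinical: list[ClinicalRecord]
    paired_patients: list[str]
    relapse_variants: list[VariantRecord]
    relapse_loss: dict[str, bool]


def simulate_study(config: SimulationConfig, panel: AmpliconPanel | None = None) -> StudyData:
    """Generate every input of one study run under a single seed:
    a panel of normals, tumor coverage with purity-diluted CDKN2A losses,
    raw variant tables with FFPE artefacts, relapse samples for the first
    ``n_paired`` patients, and clinical follow-up with a MYC-rearrangement
    covariate hazard (none unless configured)."""
    panel = panel or build_default_panel()
    patient_ids = [f"LT_{i + 1:02d}" for i in range(config.n_patients)]

    rng = _rng(config, 51)
    lo, hi = config.tumor_purity_range
    purity = rng.uniform(lo, hi, size=config.n_patients)
    has_loss = rng.random(config.n_patients) < config.cdkn2a_loss_prob
    biallelic = rng.random(config.n_patients) < 0.5
    loss_truth = pd.DataFrame(
        {
            "sample_id": patient_ids,
            "loss": np.where(~has_loss, "none",
                             np.where(biallelic, "biallelic", "monoallelic")),
            "purity": np.round(purity, 3),
        }
    )
    tumors, _ = simulate_coverage(config, panel, loss_truth)
    normals = simulate_normals(config, panel)
    variants, variant_truth = simulate_variants(config, panel, patient_ids)

    paired = patient_ids[: config.n_paired]
    primary_for_pairs = [v for v in variants if v.sample_id in set(paired)]
    loss_map = {r.sample_id: r.loss != "none"
                for r in loss_truth.itertuples() if r.sample_id in set(paired)}
    relapse_variants, relapse_loss = simulate_paired(
        config, primary_for_pairs, primary_loss=loss_map, panel=panel)

    myc = pd.DataFrame(
        {"MYC_rearranged": (rng.random(config.n_patients) < 0.25).astype(float)},
        index=patient_ids)
    clinical = simulate_survival(config, myc)
    return StudyData(
        panel=panel, normals=normals, tumors=tumors, loss_truth=loss_truth,
        variants=variants, variant_truth=variant_truth, clinical=clinical,
        paired_patients=paired, relapse_variants=relapse_variants,
        relapse_loss=relapse_loss,
    )
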