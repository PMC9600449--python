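"""Core domain types for targeted lymphoma-panel profiling.

The panel is an amplicon-based design: each gene is tiled by one or more
PCR amplicons whose read counts serve as copy-number proxies, while small
variants are reported per sample with pathogenicity annotations. Clinical
follow-up is carried as durations (months from diagnosis), never calendar
dates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MUTATION_TYPES = frozenset(
    {
        "nonsynonymous",
        "nonsense",
        "frameshift",
        "splice",
        "inframe_indel",
        "synonymous",
        "other",
    }
)

TREATMENTS = frozenset({"local", "systemic", "combined", "none"})
RESPONSES = frozenset({"CR", "refractory_progressive"})
DEATH_CAUSES = frozenset({"lymphoma", "other", "alive"})


@dataclass(frozen=True)
class Amplicon:
    """One PCR-targeted interval; coordinates are 0-based half-open."""

    amplicon_id: str
    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"amplicon {self.amplicon_id}: start {self.start} >= end {self.end}"
            )
        if self.start < 0:
            raise ValueError(f"amplicon {self.amplicon_id}: negative start")


class AmpliconPanel:
    """Ordered amplicon intervals, the coordinate frame for coverage.

    Amplicons are stored sorted by (chrom, start, amplicon_id); within one
    gene this yields genomic order, which the consecutive-amplicon CNV rule
    relies on. ``gene_index`` maps gene -> positions into ``amplicons``.
    """

    def __init__(self, amplicons: Iterable[Amplicon]) -> None:
        amps = sorted(amplicons, key=lambda a: (a.chrom, a.start, a.amplicon_id))
        if not amps:
            raise ValueError("no amplicons")
        ids = [a.amplicon_id for a in amps]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate amplicon_id: {', '.join(dup)}")
        self.amplicons: list[Amplicon] = amps
        self.gene_index: dict[str, list[int]] = {}
        for i, a in enumerate(amps):
            self.gene_index.setdefault(a.gene, []).append(i)

    @property
    def amplicon_ids(self) -> list[str]:
        return [a.amplicon_id for a in self.amplicons]

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_index)

    def gene_amplicons(self, gene: str) -> list[Amplicon]:
        """Amplicons of one gene in genomic order."""
        if gene not in self.gene_index:
            raise KeyError(f"gene {gene!r} not in panel")
        return [self.amplicons[i] for i in self.gene_index[gene]]

    def amplicon_counts_per_gene(self) -> dict[str, int]:
        return {g: len(ix) for g, ix in self.gene_index.items()}

    def __len__(self) -> int:
        return len(self.amplicons)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AmpliconPanel):
            return NotImplemented
        return self.amplicons == other.amplicons


@dataclass
class CoverageMatrix:
    """Raw per-amplicon read counts, amplicons x samples.

    ``df`` is integer-valued with amplicon_id index and sample_id columns.
    Counts are raw, never normalized.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates or self.df.columns.has_duplicates:
            raise ValueError("duplicate amplicon_id or sample_id in coverage matrix")
        vals = self.df.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("coverage counts must be integers")
            self.df = self.df.astype(np.int64)
        if (self.df.to_numpy() < 0).any():
            raise ValueError("coverage counts must be >= 0")

    @property
    def amplicon_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    def sample(self, sample_id: str) -> pd.Series:
        return self.df[sample_id]

    def validate_against_panel(self, panel: AmpliconPanel) -> None:
        unknown = set(self.df.index) - set(panel.amplicon_ids)
        if unknown:
            raise ValueError(
                f"coverage rows not in panel: {', '.join(sorted(unknown))}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """One annotated small variant; positions are 1-based (VCF convention).

    ``variant_class`` is the 5-tier pathogenicity class (5=pathogenic,
    4=likely pathogenic, 3=unknown significance).
    ``n_damaging_predictions`` counts damaging calls among the four
    predictors used for class-3 adjudication (SIFT, PolyPhen, likelihood
    ratio test, MutationTaster); None means not annotated, which is distinct
    from an annotated 0.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    depth: int
    variant_class: int
    protein_change: str = ""
    cadd_phred: float | None = None
    n_damaging_predictions: int | None = None
    mutation_type: str = "other"

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(
                f"{self.sample_id} {self.gene} {self.chrom}:{self.pos}: "
                f"vaf {self.vaf} outside [0, 1]"
            )
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.variant_class not in (1, 2, 3, 4, 5):
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.n_damaging_predictions is not None and not (
            0 <= self.n_damaging_predictions <= 4
        ):
            raise ValueError("n_damaging_predictions must be in 0..4")
        if self.mutation_type not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation_type {self.mutation_type!r}")

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in "ACGT"
            and self.alt in "ACGT"
        )


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient clinical follow-up, all times in months from diagnosis.

    ``follow_up_months`` is time to death or last contact;
    ``time_to_event_months`` is time to relapse/progression (or equals
    follow-up when no progression occurred). A lymphoma death implies both
    the overall-survival and disease-specific events.
    """

    patient_id: str
    treatment: str
    response: str
    relapse_flag: bool
    time_to_event_months: float
    follow_up_months: float
    os_event: bool
    dss_event: bool
    pfs_event: bool
    death_cause: str
    myc_rearranged: bool | None = None

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if self.death_cause not in DEATH_CAUSES:
            raise ValueError(f"unknown death_cause {self.death_cause!r}")
        if self.time_to_event_months < 0 or self.follow_up_months < 0:
            raise ValueError("times must be >= 0")
        if self.death_cause == "lymphoma" and not (self.os_event and self.dss_event):
            raise ValueError(
                f"{self.patient_id}: lymphoma death requires os_event and dss_event"
            )
        if self.death_cause == "other" and not self.os_event:
            raise ValueError(f"{self.patient_id}: other-cause death requires os_event")


@dataclass
class FilterConfig:
    """Thresholds of the QC/filtering cascade.

    Defaults follow the validated panel workflow: samples need a mean
    amplicon read count >= 100 and a Ts:Tv ratio <= 5 (FFPE-artefact
    guard); variants need VAF >= 10% unless they are a driver hotspot;
    class-3 variants additionally need a high CADD-PHRED or >= 2 damaging
    predictor calls. The CNV rule uses a 99% normal-panel interval and
    requires more than 2 (i.e. >= 3) consecutive amplicons below it.
    """

    read_count_min: float = 100.0
    tstv_max: float = 5.0
    vaf_min: float = 0.10
    cadd_threshold: float = 20.0
    min_damaging_predictions: int = 2
    ci_level: float = 0.99
    consecutive_min: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.consecutive_min < 1:
            raise ValueError("consecutive_min must be >= 1")
        if not 0 <= self.vaf_min <= 1:
            raise ValueError("vaf_min must be in [0, 1]")
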