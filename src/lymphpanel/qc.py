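"""Sample- and variant-level QC filtering for the panel workflow.

Two sample-level exclusion rules guard against failed FFPE libraries: a
mean amplicon read count below 100, and a transition:transversion ratio
above 5 (cytosine deamination in FFPE tissue inflates C>T/G>A
transitions). Variant-level retention then requires VAF >= 10% and a
reportable pathogenicity class — class 4/5 outright, class 3 only when
CADD-PHRED is high or at least two of the four in-silico predictors
(SIFT, PolyPhen, likelihood ratio test, MutationTaster) call it damaging.
The two driver hotspots, MYD88 L265P and CD79B Y196, are exempt from the
VAF floor and reported at any positive VAF.

Ts:Tv is computed on the raw (pre-VAF-filter) calls of a sample; QC
reports carry that provenance flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import FilterConfig, VariantRecord

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


@dataclass
class TsTvResult:
    """Transition/transversion tally over the SNVs of one sample."""

    n_transitions: int
    n_transversions: int

    @property
    def ratio(self) -> float | None:
        """Ts/Tv, or None (undefined) when no transversions were seen."""
        if self.n_transversions == 0:
            return None
        return self.n_transitions / self.n_transversions

    @property
    def undefined(self) -> bool:
        return self.n_transversions == 0


@dataclass
class SampleQCReport:
    sample_id: str
    mean_read_count: float
    tstv: TsTvResult
    n_raw_variants: int
    fail_reasons: list[str] = field(default_factory=list)
    tstv_computed_on: str = "raw_pre_filter_calls"

    @property
    def passed(self) -> bool:
        return not self.fail_reasons

    @property
    def tstv_ratio(self) -> float | None:
        return self.tstv.ratio


@dataclass(frozen=True)
class FilterDecision:
    """One per-variant entry of the decision log."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    retained: bool
    rule: str


def tstv_counts(variants: Iterable[VariantRecord]) -> TsTvResult:
    """Count transitions (A<->G, C<->T) and transversions among SNVs;
    non-SNVs (indels, MNVs) are ignored."""
    ts = tv = 0
    for v in variants:
        if not v.is_snv:
            continue
        if (v.ref, v.alt) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    return TsTvResult(ts, tv)


def tstv_ratio(variants: Iterable[VariantRecord]) -> float | None:
    """Ts:Tv ratio of a sample's SNVs; None when undefined (no
    transversions). The caller decides how undefined is treated — with
    >= 1 transition it fails the artefact rule (ratio effectively
    infinite), with zero SNVs it is neutral."""
    return tstv_counts(variants).ratio


def sample_qc(
    sample_id: str,
    variants: Sequence[VariantRecord],
    coverage_counts: pd.Series | np.ndarray | Sequence[float] | None,
    config: FilterConfig | None = None,
) -> SampleQCReport:
    """Apply the two sample-exclusion rules.

    ``coverage_counts`` are the sample's raw counts over the panel
    amplicons; their mean is the sample's read-count statistic. A sample
    fails on low_read_count when that mean is below ``read_count_min`` and
    on high_tstv when Ts:Tv exceeds ``tstv_max`` (or is undefined with at
    least one transition observed).
    """
    config = config or FilterConfig()
    if coverage_counts is None:
        raise ValueError(f"sample {sample_id!r}: no coverage available")
    counts = np.asarray(coverage_counts, dtype=float)
    if counts.size == 0:
        raise ValueError(f"sample {sample_id!r}: no coverage available")
    mean_count = float(counts.mean())

    tstv = tstv_counts(variants)
    reasons = []
    if mean_count < config.read_count_min:
        reasons.append("low_read_count")
    if tstv.undefined:
        if tstv.n_transitions >= 1:  # all-transition sample: ratio -> inf
            reasons.append("high_tstv")
    elif tstv.ratio > config.tstv_max:
        reasons.append("high_tstv")
    return SampleQCReport(
        sample_id=sample_id,
        mean_read_count=mean_count,
        tstv=tstv,
        n_raw_variants=len(variants),
        fail_reasons=reasons,
    )


def is_hotspot(v: VariantRecord) -> bool:
    """The VAF-exempt driver hotspots: MYD88 L265P and CD79B Y196 (any
    substitution at that residue, Y196S/Y196H/...)."""
    if v.gene == "MYD88" and v.protein_change == "L265P":
        return True
    if v.gene == "CD79B" and v.protein_change.startswith("Y196"):
        return True
    return False


def _classify(v: VariantRecord, config: FilterConfig) -> tuple[bool, str]:
    """Retention predicate with the rule that fired."""
    if is_hotspot(v) and v.vaf > 0.0:
        return True, "hotspot_exception"
    if v.vaf < config.vaf_min:
        return False, "below_vaf_min"
    if v.variant_class in (4, 5):
        return True, "class_4_5"
    if v.variant_class == 3:
        cadd_known = v.cadd_phred is not None
        preds_known = v.n_damaging_predictions is not None
        if not cadd_known and not preds_known:
            return False, "class_3_unevaluable"
        if cadd_known and v.cadd_phred >= config.cadd_threshold:
            return True, "class_3_high_cadd"
        if preds_known and v.n_damaging_predictions >= config.min_damaging_predictions:
            return True, "class_3_multiple_predictors"
        return False, "class_3_not_pathogenic"
    return False, "class_1_2_not_reportable"


def filter_variants(
    variants: Sequence[VariantRecord],
    config: FilterConfig | None = None,
) -> tuple[list[VariantRecord], list[FilterDecision]]:
    """Apply the variant-retention cascade; every decision is logged with
    the rule that fired. Output is a subset of the input in input order;
    the operation is idempotent."""
    config = config or FilterConfig()
    retained: list[VariantRecord] = []
    log: list[FilterDecision] = []
    for v in variants:
        keep, rule = _classify(v, config)
        if keep:
            retained.append(v)
        log.append(
            FilterDecision(
                sample_id=v.sample_id,
                gene=v.gene,
                chrom=v.chrom,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                retained=keep,
                rule=rule,
            )
        )
    return retained, log


def decisions_to_frame(log: Sequence[FilterDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "gene": d.gene,
                "chrom": d.chrom,
                "pos": d.pos,
                "ref": d.ref,
                "alt": d.alt,
                "retained": d.retained,
                "rule": d.rule,
            }
            for d in log
        ],
        columns=["sample_id", "gene", "chrom", "pos", "ref", "alt", "retained", "rule"],
    )


def qc_reports_to_frame(reports: Sequence[SampleQCReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "mean_read_count": r.mean_read_count,
                "tstv_ratio": r.tstv_ratio,
                "tstv_undefined": r.tstv.undefined,
                "n_raw_variants": r.n_raw_variants,
                "passed": r.passed,
                "fail_reasons": ";".join(r.fail_reasons),
            }
            for r in reports
        ]
    )
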