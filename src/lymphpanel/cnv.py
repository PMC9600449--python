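"""Single-gene copy-number loss calling from amplicon read counts.

The copy-number proxy is normalized coverage: each library's amplicon
counts divided by the median count over ALL panel amplicons of that
library (depth invariance). Systematic per-amplicon efficiency
differences are removed with a panel of normals: per target-gene
amplicon, the mean log2 normalized coverage across the normal libraries
is the efficiency factor, and the between-library spread yields an
interval at ``ci_level`` on the factor-normalized scale. A gene is
called lost when more than 2 (i.e. >= 3) consecutive amplicons, in
genomic order, fall below the lower interval bound. Only the lower bound
triggers a call; amplification is out of scope.

Interval construction (``method``):
  * ``"t_prediction"`` (default): mean +/- t_{n-1,(1+ci)/2} * s * sqrt(1+1/n)
    on the log2 scale — a prediction interval for one new library, which
    attains nominal coverage on held-out normals at small n;
  * ``"z"``: mean +/- z * s, the plain normal approximation (ignores
    estimation error; under-covers at n ~ 18).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import AmpliconPanel, CoverageMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalPanelModel:
    """Per-amplicon efficiency factors and interval bounds for one gene.

    ``factor`` is 2**(mean log2 normalized coverage) per amplicon;
    ``ci_lower``/``ci_upper`` are bounds on the factor-normalized scale
    (so the center is 1 and ci_lower < 1 < ci_upper). Fit only from
    libraries labelled normal.
    """

    gene: str
    amplicon_ids: list[str]
    chroms: list[str]
    factor: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    sd_log2: np.ndarray
    n_libraries: int
    ci_level: float
    method: str

    def __post_init__(self) -> None:
        if not ((self.ci_lower < 1.0) & (1.0 < self.ci_upper)).all():
            raise ValueError("interval bounds must bracket the normalized center 1")


@dataclass
class CnvCall:
    sample_id: str
    gene: str
    normalized: pd.Series  # factor-normalized coverage per gene amplicon
    below_ci: pd.Series
    max_run_below: int

    @property
    def loss_called(self) -> bool:
        return self.max_run_below >= self._consecutive_min

    _consecutive_min: int = 3


def normalize_library(counts: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Divide one library's amplicon counts by the median over all panel
    amplicons of that library. Dimensionless; median of output is 1."""
    arr = np.asarray(counts, dtype=float)
    med = np.median(arr)
    if med <= 0:
        if (arr > 0).any():
            raise ValueError("library median is zero; too many dropped amplicons")
        raise ValueError("empty library")
    out = arr / med
    if isinstance(counts, pd.Series):
        return pd.Series(out, index=counts.index)
    return out


def fit_normal_panel(
    normals: CoverageMatrix,
    panel: AmpliconPanel,
    gene: str = "CDKN2A",
    ci_level: float = 0.99,
    method: str = "t_prediction",
) -> NormalPanelModel:
    """Fit per-amplicon factors and interval bounds from normal libraries.

    Libraries with zero coverage at an amplicon are excluded for that
    amplicon (with a warning); fewer than 3 usable libraries anywhere is
    an error.
    """
    if method not in ("t_prediction", "z"):
        raise ValueError(f"unknown interval method {method!r}")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    normals.validate_against_panel(panel)
    if len(normals.sample_ids) < 3:
        raise ValueError(
            f"need >= 3 normal libraries, got {len(normals.sample_ids)}"
        )
    gene_amps = panel.gene_amplicons(gene)
    amp_ids = [a.amplicon_id for a in gene_amps]
    missing = [a for a in amp_ids if a not in normals.df.index]
    if missing:
        raise ValueError(f"normals lack amplicons: {', '.join(missing)}")

    # normalize each library over the FULL panel, then restrict to the gene
    norm_cols = {}
    for sid in normals.sample_ids:
        norm_cols[sid] = normalize_library(normals.df[sid])
    norm = pd.DataFrame(norm_cols).loc[amp_ids]

    means = np.empty(len(amp_ids))
    sds = np.empty(len(amp_ids))
    halfwidths = np.empty(len(amp_ids))
    for i, amp in enumerate(amp_ids):
        vals = norm.loc[amp].to_numpy(dtype=float)
        usable = vals > 0
        if usable.sum() < len(vals):
            logger.warning(
                "amplicon %s: excluding %d zero-coverage normal librar%s",
                amp, int((~usable).sum()), "y" if (~usable).sum() == 1 else "ies",
            )
        vals = vals[usable]
        n = len(vals)
        if n < 3:
            raise ValueError(f"amplicon {amp}: fewer than 3 usable normal libraries")
        log2v = np.log2(vals)
        means[i] = log2v.mean()
        sds[i] = log2v.std(ddof=1)
        alpha = (1.0 + ci_level) / 2.0
        if method == "t_prediction":
            halfwidths[i] = stats.t.ppf(alpha, n - 1) * sds[i] * np.sqrt(1.0 + 1.0 / n)
        else:
            halfwidths[i] = stats.norm.ppf(alpha) * sds[i]
        # noiseless normals give sd 0; keep the bounds strictly bracketing
        halfwidths[i] = max(halfwidths[i], 1e-9)

    return NormalPanelModel(
        gene=gene,
        amplicon_ids=amp_ids,
        chroms=[a.chrom for a in gene_amps],
        factor=np.power(2.0, means),
        ci_lower=np.power(2.0, -halfwidths),
        ci_upper=np.power(2.0, halfwidths),
        sd_log2=sds,
        n_libraries=len(normals.sample_ids),
        ci_level=ci_level,
        method=method,
    )


def max_run_below(below: np.ndarray, chroms: list[str] | None = None) -> int:
    """Longest run of True in genomic order; runs never join across
    chromosomes."""
    best = cur = 0
    prev_chrom = None
    for i, flag in enumerate(below):
        chrom = chroms[i] if chroms is not None else None
        if chrom != prev_chrom:
            cur = 0
        prev_chrom = chrom
        cur = cur + 1 if flag else 0
        best = max(best, cur)
    return best


def call_loss(
    sample_id: str,
    sample_counts: pd.Series,
    model: NormalPanelModel,
    consecutive_min: int = 3,
) -> CnvCall:
    """Call loss of the model's gene for one tumor library.

    ``sample_counts`` must span the full panel (the median normalizer uses
    all amplicons). The library is normalized, divided by the per-amplicon
    factor, and compared against the lower interval bound; a loss is
    called when >= ``consecutive_min`` consecutive gene amplicons lie
    below it.
    """
    missing = [a for a in model.amplicon_ids if a not in sample_counts.index]
    if missing:
        raise ValueError(
            f"sample {sample_id!r} missing amplicon(s): {', '.join(missing)}"
        )
    norm_full = normalize_library(sample_counts)
    normalized = norm_full.loc[model.amplicon_ids] / model.factor
    below = normalized.to_numpy() < model.ci_lower
    run = max_run_below(below, model.chroms)
    return CnvCall(
        sample_id=sample_id,
        gene=model.gene,
        normalized=normalized,
        below_ci=pd.Series(below, index=model.amplicon_ids),
        max_run_below=run,
        _consecutive_min=consecutive_min,
    )


def call_cohort(
    tumors: CoverageMatrix,
    model: NormalPanelModel,
    consecutive_min: int = 3,
) -> pd.DataFrame:
    """Loss calls for every sample of a coverage matrix; one row per
    sample with the per-amplicon run statistic."""
    rows = []
    for sid in tumors.sample_ids:
        call = call_loss(sid, tumors.df[sid], model, consecutive_min)
        rows.append(
            {
                "sample_id": sid,
                "gene": model.gene,
                "max_run_below": call.max_run_below,
                "n_below_ci": int(call.below_ci.sum()),
                "loss_called": call.loss_called,
            }
        )
    return pd.DataFrame(rows)
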