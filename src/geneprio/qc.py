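"""RNA-seq sample quality control.

Two passes, applied once each (no iterative re-fencing):

1. drop samples with fewer than 6 million mapped reads (configurable floor,
   strict less-than);
2. within each tissue, compute pairwise Euclidean distances between sample
   profiles on the log2(TPM+1) scale, summarize each sample by its mean
   distance to its same-tissue peers, and drop samples whose summary falls
   outside Tukey's fences [Q1 - k*IQR, Q3 + k*IQR] with k = 3 (the "far
   outlier" setting).

Quartiles use linear interpolation between order statistics (the common
"type 7" rule); the convention is fixed here for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .types import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 6_000_000
DEFAULT_FENCE_K = 3.0


@dataclass(frozen=True)
class FenceBounds:
    """Tukey's fences computed from a sample of observations."""

    q1: float
    q3: float
    k: float

    @property
    def lower(self) -> float:
        return self.q1 - self.k * (self.q3 - self.q1)

    @property
    def upper(self) -> float:
        return self.q3 + self.k * (self.q3 - self.q1)

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


@dataclass
class TissueReport:
    tissue: str
    kept: list[str]
    removed: list[str]
    distances: dict[str, float]  # per-sample summary statistic
    bounds: FenceBounds | None  # None when the tissue was too small to fence


@dataclass
class OutlierReport:
    per_tissue: dict[str, TissueReport] = field(default_factory=dict)

    @property
    def removed(self) -> list[str]:
        return [s for rep in self.per_tissue.values() for s in rep.removed]

    @property
    def kept(self) -> list[str]:
        return [s for rep in self.per_tissue.values() for s in rep.kept]


def filter_low_mapped(
    matrix: ExpressionMatrix, min_reads: int = DEFAULT_MIN_READS
) -> ExpressionMatrix:
    """Remove samples whose mapped-read count is strictly below ``min_reads``."""
    if "mapped_reads" not in matrix.meta.columns:
        raise ValueError("sample metadata lacks a 'mapped_reads' column")
    keep = [
        s for s in matrix.sample_ids
        if int(matrix.meta.loc[s, "mapped_reads"]) >= min_reads
    ]
    if not keep:
        raise ValueError(
            f"empty matrix: all {matrix.n_samples} samples have mapped reads "
            f"< {min_reads}"
        )
    dropped = matrix.n_samples - len(keep)
    if dropped:
        logger.info("mapped-read filter removed %d of %d samples", dropped,
                    matrix.n_samples)
    return matrix.subset_samples(keep)


def tukey_fences(values: np.ndarray | list[float], k: float = DEFAULT_FENCE_K) -> FenceBounds:
    """Fence bounds from >= 4 observations; quartiles by linear interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError(f"need at least 4 values for fences, got {values.size}")
    if k < 0:
        raise ValueError(f"k must be nonnegative, got {k}")
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation (type 7)
    return FenceBounds(q1=float(q1), q3=float(q3), k=float(k))


def detect_tissue_outliers(
    matrix: ExpressionMatrix,
    k: float = DEFAULT_FENCE_K,
    summary: str = "mean",
    log_transform: bool = True,
) -> OutlierReport:
    """Flag within-tissue outliers by fencing per-sample mean peer distance.

    Tissues with fewer than 4 samples pass through untouched (fences need
    quartiles). ``summary`` may be ``mean`` (default) or ``median`` — the
    reduction of a sample's pairwise distances to a single statistic.
    """
    if summary not in {"mean", "median"}:
        raise ValueError(f"summary must be 'mean' or 'median', got {summary!r}")
    reduce = np.mean if summary == "mean" else np.median
    X = matrix.log2_values() if log_transform else matrix.values
    report = OutlierReport()
    for tissue in matrix.tissues():
        samples = matrix.samples_of_tissue(tissue)
        if len(samples) < 4:
            logger.warning(
                "tissue %r has %d samples (<4); outlier fencing skipped",
                tissue, len(samples),
            )
            report.per_tissue[tissue] = TissueReport(
                tissue, kept=list(samples), removed=[], distances={}, bounds=None
            )
            continue
        profiles = X[samples].to_numpy().T  # samples x genes
        dist = squareform(pdist(profiles, metric="euclidean"))
        # mean/median over the n-1 peers, excluding self-distance 0
        n = len(samples)
        offdiag = dist[~np.eye(n, dtype=bool)].reshape(n, n - 1)
        summaries = reduce(offdiag, axis=1)
        bounds = tukey_fences(summaries, k=k)
        kept, removed = [], []
        for s, d in zip(samples, summaries):
            (kept if bounds.contains(d) else removed).append(s)
        if removed:
            logger.info("tissue %r: removed %s (fences [%.3g, %.3g])",
                        tissue, removed, bounds.lower, bounds.upper)
        report.per_tissue[tissue] = TissueReport(
            tissue, kept=kept, removed=removed,
            distances=dict(zip(samples, map(float, summaries))), bounds=bounds,
        )
    return report


def apply_outlier_report(matrix: ExpressionMatrix, report: OutlierReport) -> ExpressionMatrix:
    removed = set(report.removed)
    keep = [s for s in matrix.sample_ids if s not in removed]
    if not keep:
        raise ValueError("empty matrix: outlier removal deleted every sample")
    return matrix.subset_samples(keep)


def run_qc(
    matrix: ExpressionMatrix,
    min_reads: int = DEFAULT_MIN_READS,
    k: float = DEFAULT_FENCE_K,
) -> tuple[ExpressionMatrix, OutlierReport]:
    """Mapped-read floor then per-tissue fence pass; returns the cleaned matrix."""
    filtered = filter_low_mapped(matrix, min_reads=min_reads)
    report = detect_tissue_outliers(filtered, k=k)
    return apply_outlier_report(filtered, report), report


def tissue_mean_expression(matrix: ExpressionMatrix, tissue: str) -> "np.ndarray":
    """Per-gene mean log2(TPM+1) over the samples of one tissue.

    This is the Expression feature source: the gene's typical abundance in
    the tissue the trait is read out in.
    """
    samples = matrix.samples_of_tissue(tissue)
    if not samples:
        raise ValueError(
            f"unknown tissue {tissue!r}; available: {matrix.tissues()}"
        )
    return matrix.log2_values()[samples].mean(axis=1).to_numpy()
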