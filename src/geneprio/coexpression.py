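"""Weighted co-expression network analysis, pared down to what the feature
pipeline needs.

Adjacency is the soft-thresholded absolute Pearson correlation
``a_ij = |cor(x_i, x_j)|**beta``; from it the unsigned topological overlap
(TOM) measures how much two genes share network neighborhood:

    tom_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity ``k_i = sum_{u != i} a_iu`` and the shared-neighbor sum
over ``u != i, j``. Modules come from average-linkage hierarchical
clustering of ``1 - TOM``, a static tree cut, a minimum-size filter
(default 30) and a merge of modules whose eigengenes correlate above
``1 - merge_threshold`` (default 0.2). The eigengene is the first principal
component score of the module's standardized expression, with its sign fixed
so it correlates positively with the module's mean expression profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .types import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_BETA = 6
DEFAULT_MIN_MODULE_SIZE = 30
DEFAULT_MERGE_THRESHOLD = 0.2
DEFAULT_CUT_FRACTION = 0.99  # static cut at this fraction of the max merge height
DEFAULT_MAX_MISSING_FRAC = 0.5


@dataclass
class AdjacencyMatrix:
    gene_ids: list[str]
    a: np.ndarray
    beta: int


@dataclass
class ModuleAssignment:
    """Gene -> module labels (0 = unassigned) plus per-module eigengenes."""

    labels: dict[str, int]
    eigengenes: dict[int, np.ndarray]  # module -> score vector over samples
    sample_ids: list[str]
    sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sizes:
            self.sizes = {
                m: sum(1 for v in self.labels.values() if v == m)
                for m in self.eigengenes
            }

    def module_of(self, gene_id: str) -> int:
        return self.labels.get(gene_id, 0)

    @property
    def n_modules(self) -> int:
        return len(self.eigengenes)


def filter_genes(
    matrix: ExpressionMatrix, max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC
) -> ExpressionMatrix:
    """Drop genes with zero variance or too many missing values."""
    vals = matrix.values
    missing_frac = vals.isna().mean(axis=1)
    variance = vals.var(axis=1, ddof=0)
    keep = (variance > 0) & (missing_frac <= max_missing_frac)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("gene filter removed %d of %d genes", dropped, matrix.n_genes)
    return ExpressionMatrix(vals.loc[keep], matrix.meta)


def adjacency(matrix: ExpressionMatrix, beta: int = DEFAULT_BETA) -> AdjacencyMatrix:
    """Soft-power adjacency |cor|^beta on log2(TPM+1) profiles."""
    if beta < 1:
        raise ValueError(f"soft power beta must be >= 1, got {beta}")
    if matrix.n_samples < 3:
        raise ValueError(f"need >= 3 samples for correlations, got {matrix.n_samples}")
    X = matrix.log2_values().to_numpy()
    cor = np.corrcoef(X)
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    a = np.abs(cor) ** beta
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(gene_ids=matrix.gene_ids, a=a, beta=beta)


def topological_overlap(adj: AdjacencyMatrix) -> np.ndarray:
    """Unsigned TOM of an adjacency matrix (diagonal = 1)."""
    a = adj.a
    n = a.shape[0]
    # shared-neighbor sums over all u, corrected to exclude u = i and u = j
    full = a @ a
    shared = full - a * np.diag(a)[np.newaxis, :] - np.diag(a)[:, np.newaxis] * a
    # the two subtractions both remove the u=i=j term on the diagonal; the
    # diagonal is overwritten below so it does not matter
    k = a.sum(axis=1) - np.diag(a)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def _eigengene(X: np.ndarray) -> np.ndarray:
    """First PC score vector over samples of genes x samples expression.

    Genes are standardized first; the sign is fixed so the eigengene
    correlates positively with the module's mean standardized expression.
    """
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd  # genes x samples
    # first right singular vector = PC1 scores over samples
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    pc1 = vt[0]
    mean_profile = Z.mean(axis=0)
    if np.dot(pc1, mean_profile) < 0:
        pc1 = -pc1
    return pc1


def detect_modules(
    tom: np.ndarray,
    matrix: ExpressionMatrix,
    min_size: int = DEFAULT_MIN_MODULE_SIZE,
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
    cut_fraction: float = DEFAULT_CUT_FRACTION,
) -> ModuleAssignment:
    """Cluster 1-TOM, cut, size-filter, and merge similar modules.

    The tree is cut statically at ``cut_fraction`` of the maximum merge
    height; clusters below ``min_size`` become unassigned (label 0); module
    pairs whose eigengene correlation is >= ``1 - merge_threshold`` are
    merged greedily (closest pair first) until none remain.
    """
    gene_ids = matrix.gene_ids
    n = len(gene_ids)
    if tom.shape != (n, n):
        raise ValueError(f"TOM shape {tom.shape} does not match {n} genes")
    X = matrix.log2_values().to_numpy()

    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dissim, checks=False), method="average")
    max_height = Z[:, 2].max() if len(Z) else 0.0
    if max_height <= 0:
        raw = np.ones(n, dtype=int)
    else:
        raw = fcluster(Z, t=cut_fraction * max_height, criterion="distance")

    # size filter, relabel surviving clusters 1..K in first-appearance order
    labels = np.zeros(n, dtype=int)
    next_label = 1
    for cl in dict.fromkeys(raw):  # preserves order of first appearance
        members = np.flatnonzero(raw == cl)
        if len(members) >= min_size:
            labels[members] = next_label
            next_label += 1
    module_ids = sorted(set(labels) - {0})
    if not module_ids:
        logger.warning("no module reached min_size=%d; all genes unassigned", min_size)
        return ModuleAssignment(
            labels={g: 0 for g in gene_ids}, eigengenes={}, sample_ids=matrix.sample_ids
        )

    eigen = {m: _eigengene(X[labels == m]) for m in module_ids}

    # greedy merge of eigengene-similar modules (dissimilarity 1-cor < threshold)
    while len(eigen) > 1:
        ids = sorted(eigen)
        best, best_cor = None, -np.inf
        for i, mi in enumerate(ids):
            for mj in ids[i + 1:]:
                c = float(np.corrcoef(eigen[mi], eigen[mj])[0, 1])
                if c > best_cor:
                    best_cor, best = c, (mi, mj)
        if best_cor < 1.0 - merge_threshold:
            break
        mi, mj = best
        logger.info("merging modules %d and %d (eigengene cor %.3f)", mi, mj, best_cor)
        labels[labels == mj] = mi
        eigen[mi] = _eigengene(X[labels == mi])
        del eigen[mj]

    # final relabel to consecutive 1..K
    remap = {old: new for new, old in enumerate(sorted(eigen), start=1)}
    labels = np.array([remap.get(l, 0) for l in labels])
    eigen = {remap[m]: v for m, v in eigen.items()}
    return ModuleAssignment(
        labels=dict(zip(gene_ids, map(int, labels))),
        eigengenes=eigen,
        sample_ids=matrix.sample_ids,
    )


def module_tissue_correlation(
    modules: ModuleAssignment, matrix: ExpressionMatrix, tissue: str
) -> dict[int, float]:
    """Pearson correlation of each module eigengene with the tissue indicator.

    The indicator is 1 for samples of ``tissue`` and 0 otherwise, over all
    samples. A constant indicator (tissue covers none or all samples) makes
    the correlation undefined; 0 is returned with a warning.
    """
    indicator = (matrix.meta["tissue"] == tissue).to_numpy(dtype=float)
    out: dict[int, float] = {}
    if indicator.std() == 0:
        logger.warning(
            "tissue %r covers %s samples; module-tissue correlation undefined, "
            "returning 0", tissue, "all" if indicator.all() else "no",
        )
        return {m: 0.0 for m in modules.eigengenes}
    for m, eg in modules.eigengenes.items():
        if np.std(eg) == 0:
            logger.warning("module %d eigengene is constant; correlation set to 0", m)
            out[m] = 0.0
        else:
            out[m] = float(np.corrcoef(eg, indicator)[0, 1])
    return out


def write_modules(modules: ModuleAssignment, path) -> None:
    df = pd.DataFrame(
        sorted(modules.labels.items()), columns=["gene_id", "module"]
    )
    df.to_csv(path, sep="\t", index=False)
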