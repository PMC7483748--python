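"""Assembly of the 14-feature vector for (gene, trait, tissue) triples.

Per triple:

* 10 genome features — SNP and indel counts in five gene-relative regions
  (upstream flank, downstream flank, intron, synonymous, nonsynonymous).
  Flanks default to 2 kb and are strand-aware: "upstream" of a minus-strand
  gene lies at higher coordinates. Genic categories are trusted from the
  variant annotation; the flank side is recomputed from position and strand.
* 2 transcriptome features — Expression, the gene's mean log2(TPM+1) in the
  target tissue; Module, the correlation of the gene's co-expression module
  eigengene with the tissue indicator (0 for unassigned genes).
* 2 literature features — counts of trait-matched QTALs and QTANs
  overlapping the gene body (QTALs pre-trimmed).

Counts are integers and correlations live in [-1, 1]; models therefore see
z-scored features, with scaler parameters always learned on training data
only and applied unchanged to anything scored later.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coexpression import ModuleAssignment
from .qc import tissue_mean_expression
from .qtx import count_overlaps
from .types import (
    COUNT_REGIONS,
    FEATURE_NAMES,
    ExpressionMatrix,
    GeneModel,
    QTXRecord,
    TraitOntology,
    VariantRecord,
)

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 2_000


@dataclass
class ScalerParams:
    """Per-feature mean/sd learned on training data.

    Zero-variance features are passed through unscaled (sd treated as 1) and
    reported in ``constant``.
    """

    mean: np.ndarray
    sd: np.ndarray
    constant: list[int]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def count_variants_by_region(
    gene: GeneModel,
    variants: Sequence[VariantRecord],
    flank: int = DEFAULT_FLANK,
) -> dict[str, int]:
    """The 10 per-gene variant counts, keyed ``<Region>_<type>``.

    A variant contributes when it is annotated to this gene (or carries no
    gene id but falls in the right place). Intron/synonymous/nonsynonymous
    require the position inside the gene body; upstream/downstream require
    the position within ``flank`` bp of the body, on the side the category
    names once strand is taken into account. Category ``other`` is ignored.
    """
    counts = {f"{r.capitalize()}_{t}": 0 for r in COUNT_REGIONS for t in ("snp", "indel")}
    up_lo, up_hi = gene.start - flank, gene.start - 1
    dn_lo, dn_hi = gene.end + 1, gene.end + flank
    for v in variants:
        if v.category == "other" or v.chrom != gene.chrom:
            continue
        if v.gene_id is not None and v.gene_id != gene.gene_id:
            continue
        if v.category in {"intron", "synonymous", "nonsynonymous"}:
            if gene.start <= v.pos <= gene.end:
                counts[f"{v.category.capitalize()}_{v.variant_type}"] += 1
        else:  # upstream / downstream annotation: side recomputed by strand
            if up_lo <= v.pos <= up_hi:
                side = "Upstream" if gene.strand == "+" else "Downstream"
            elif dn_lo <= v.pos <= dn_hi:
                side = "Downstream" if gene.strand == "+" else "Upstream"
            else:
                continue
            counts[f"{side}_{v.variant_type}"] += 1
    return counts


@dataclass
class FeatureSources:
    """Everything build_feature_vector needs, bundled once per run."""

    genes: Mapping[str, GeneModel]
    variants: Sequence[VariantRecord]
    expression: ExpressionMatrix
    modules: ModuleAssignment
    qtx_records: Sequence[QTXRecord]  # QTALs already trimmed
    ontology: TraitOntology | None = None
    flank: int = DEFAULT_FLANK
    trait_match: str = "subcategory"

    def __post_init__(self) -> None:
        self._variants_by_gene: dict[str | None, list[VariantRecord]] = {}
        for v in self.variants:
            self._variants_by_gene.setdefault(v.gene_id, []).append(v)
        self._expr_cache: dict[str, pd.Series] = {}
        self._module_cor_cache: dict[str, dict[int, float]] = {}

    def variants_of(self, gene_id: str) -> list[VariantRecord]:
        return self._variants_by_gene.get(gene_id, []) + self._variants_by_gene.get(None, [])

    def tissue_expression(self, tissue: str) -> pd.Series:
        if tissue not in self._expr_cache:
            self._expr_cache[tissue] = pd.Series(
                tissue_mean_expression(self.expression, tissue),
                index=self.expression.gene_ids,
            )
        return self._expr_cache[tissue]

    def module_correlations(self, tissue: str) -> dict[int, float]:
        from .coexpression import module_tissue_correlation

        if tissue not in self._module_cor_cache:
            self._module_cor_cache[tissue] = module_tissue_correlation(
                self.modules, self.expression, tissue
            )
        return self._module_cor_cache[tissue]


def build_feature_vector(
    gene_id: str, trait: str, tissue: str, sources: FeatureSources
) -> np.ndarray:
    """The 14 features, in :data:`geneprio.types.FEATURE_NAMES` order."""
    if gene_id not in sources.genes:
        raise KeyError(f"unknown gene {gene_id!r}")
    gene = sources.genes[gene_id]
    counts = count_variants_by_region(gene, sources.variants_of(gene_id), sources.flank)

    expr_series = sources.tissue_expression(tissue)
    expression = float(expr_series.get(gene_id, 0.0))
    if gene_id not in expr_series.index:
        logger.debug("gene %s absent from expression matrix; Expression=0", gene_id)

    module = sources.modules.module_of(gene_id)
    module_cor = sources.module_correlations(tissue).get(module, 0.0) if module else 0.0

    qtal = count_overlaps(
        gene, sources.qtx_records, "QTAL", trait=trait,
        ontology=sources.ontology, trait_match=sources.trait_match,
    )
    qtan = count_overlaps(
        gene, sources.qtx_records, "QTAN", trait=trait,
        ontology=sources.ontology, trait_match=sources.trait_match,
    )

    values = {**counts, "Expression": expression, "Module": module_cor,
              "QTAL": float(qtal), "QTAN": float(qtan)}
    return np.array([values[name] for name in FEATURE_NAMES], dtype=float)


def build_feature_table(
    triples: Sequence[tuple[str, str, str]], sources: FeatureSources
) -> pd.DataFrame:
    """Feature matrix for many (gene_id, trait, tissue) triples."""
    rows = [build_feature_vector(g, tr, ti, sources) for g, tr, ti in triples]
    idx = pd.MultiIndex.from_tuples(triples, names=["gene_id", "trait", "tissue"])
    return pd.DataFrame(rows, index=idx, columns=list(FEATURE_NAMES))


def standardize(
    X: np.ndarray, params: ScalerParams | None = None
) -> tuple[np.ndarray, ScalerParams]:
    """Z-score columns; fit on ``X`` unless fitted ``params`` are supplied.

    The sd is the population standard deviation (ddof=0). Constant columns
    pass through unchanged and are flagged on the returned params.
    """
    X = np.asarray(X, dtype=float)
    if params is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        constant = [int(i) for i in np.flatnonzero(sd == 0)]
        if constant:
            logger.warning("constant feature columns passed through unscaled: %s",
                           constant)
        sd = np.where(sd == 0, 1.0, sd)
        params = ScalerParams(mean=mean, sd=sd, constant=constant)
        # constant columns keep their raw values
        mean = params.mean.copy()
        mean[params.constant] = 0.0
        params = ScalerParams(mean=mean, sd=params.sd, constant=params.constant)
    return params.transform(X), params
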