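"""Domain model shared by every stage of the prioritization pipeline.

Coordinates are 1-based inclusive throughout (GFF/VCF convention); nothing
downstream converts, so readers for 0-based dialects must convert at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

STRANDS = frozenset({"+", "-"})
VARIANT_TYPES = frozenset({"snp", "indel"})
VARIANT_CATEGORIES = frozenset(
    {"upstream", "downstream", "intron", "synonymous", "nonsynonymous", "other"}
)
QTX_TYPES = frozenset({"QTAL", "QTAN", "QTAG"})

#: Fixed feature order; this order is part of the model artifact contract.
FEATURE_NAMES: tuple[str, ...] = (
    "Upstream_snp",
    "Downstream_snp",
    "Intron_snp",
    "Synonymous_snp",
    "Nonsynonymous_snp",
    "Upstream_indel",
    "Downstream_indel",
    "Intron_indel",
    "Synonymous_indel",
    "Nonsynonymous_indel",
    "Expression",
    "Module",
    "QTAL",
    "QTAN",
)

#: The five gene-relative regions counted per variant type (``other`` is ignored).
COUNT_REGIONS: tuple[str, ...] = (
    "upstream",
    "downstream",
    "intron",
    "synonymous",
    "nonsynonymous",
)


@dataclass(frozen=True)
class GeneModel:
    """A gene's genomic interval."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(
                f"gene {self.gene_id}: strand {self.strand!r} not in {sorted(STRANDS)}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class VariantRecord:
    """One (variant, annotated gene) pair.

    ``category`` is taken from the upstream annotator, not recomputed here;
    ``gene_id`` is None when the annotation carries no gene.
    """

    chrom: str
    pos: int  # 1-based
    variant_type: str
    category: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position {self.pos} < 1")
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(f"variant_type {self.variant_type!r} not in {sorted(VARIANT_TYPES)}")
        if self.category not in VARIANT_CATEGORIES:
            raise ValueError(f"category {self.category!r} not in {sorted(VARIANT_CATEGORIES)}")


@dataclass(frozen=True)
class QTXRecord:
    """A literature-derived trait-associated interval.

    QTAL = associated locus (interval), QTAN = associated nucleotide (point,
    start == end), QTAG = associated gene (experimentally supported; the
    positive-label source).
    """

    qtx_id: str
    qtx_type: str
    chrom: str
    start: int
    end: int
    trait: str
    n_reports: int = 1

    def __post_init__(self) -> None:
        if self.qtx_type not in QTX_TYPES:
            raise ValueError(f"qtx_type {self.qtx_type!r} not in {sorted(QTX_TYPES)}")
        if self.start > self.end:
            raise ValueError(f"QTX {self.qtx_id}: start {self.start} > end {self.end}")
        if self.qtx_type == "QTAN" and self.start != self.end:
            raise ValueError(f"QTAN {self.qtx_id} must be a point (start == end)")
        if self.n_reports < 1:
            raise ValueError(f"QTX {self.qtx_id}: n_reports {self.n_reports} < 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TraitOntology:
    """Maps each trait name to a (major category, subcategory) pair.

    Traits missing from the mapping resolve to ``Unclassified`` so that a
    partial ontology never blocks a pipeline run.
    """

    mapping: Mapping[str, tuple[str, str]]
    unclassified: str = "Unclassified"

    def subcategory(self, trait: str) -> str:
        return self.mapping.get(trait, (self.unclassified, self.unclassified))[1]

    def major_category(self, trait: str) -> str:
        return self.mapping.get(trait, (self.unclassified, self.unclassified))[0]

    def __contains__(self, trait: str) -> bool:
        return trait in self.mapping


class ExpressionMatrix:
    """TPM expression (genes x samples) plus per-sample metadata.

    ``meta`` is indexed by sample id, aligned to the matrix columns, with at
    least ``tissue`` (str) and ``mapped_reads`` (int) columns.
    """

    def __init__(self, values: pd.DataFrame, meta: pd.DataFrame):
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].tolist()
            raise ValueError(f"duplicated gene ids: {dups}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].tolist()
            raise ValueError(f"duplicated sample ids: {dups}")
        if (values.to_numpy() < 0).any():
            raise ValueError("negative TPM values in expression matrix")
        missing = [s for s in values.columns if s not in meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        if "tissue" not in meta.columns:
            raise ValueError("sample metadata lacks a 'tissue' column")
        self.values = values
        self.meta = meta.loc[values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def tissues(self) -> list[str]:
        return sorted(self.meta["tissue"].unique())

    def samples_of_tissue(self, tissue: str) -> list[str]:
        return list(self.meta.index[self.meta["tissue"] == tissue])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[sample_ids], self.meta.loc[sample_ids])

    def log2_values(self) -> pd.DataFrame:
        """log2(TPM + 1), the working scale for distances and summaries."""
        return np.log2(self.values + 1.0)


@dataclass(frozen=True)
class ScoredGene:
    """A candidate gene with its 0-100 score, rank and credibility call.

    ``credible`` is strictly ``score > 50``; a gene scoring exactly 50 is
    non-credible.
    """

    gene_id: str
    score: float
    rank: int

    @property
    def credible(self) -> bool:
        return self.score > 50.0


@dataclass
class TrainingSample:
    """One labelled (gene, trait) pair with its feature vector."""

    gene_id: str
    trait: str
    tissue: str
    label: int
    features: np.ndarray = field(default_factory=lambda: np.zeros(len(FEATURE_NAMES)))

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (len(FEATURE_NAMES),):
            raise ValueError(
                f"feature vector must have {len(FEATURE_NAMES)} entries, "
                f"got shape {self.features.shape}"
            )
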