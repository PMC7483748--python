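"""End-to-end orchestration: knowledgebase -> features -> model -> ranking.

This is the programmatic counterpart of chaining the CLI subcommands, and
the code path both the command-line tool and the reproduction script run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io, qc
from .coexpression import (
    DEFAULT_BETA,
    DEFAULT_MERGE_THRESHOLD,
    DEFAULT_MIN_MODULE_SIZE,
    ModuleAssignment,
    adjacency,
    detect_modules,
    filter_genes,
    topological_overlap,
)
from .features import DEFAULT_FLANK, FeatureSources, build_feature_table
from .models import FittedModel, Metrics, evaluate, prioritize, train_model
from .qtx import DEFAULT_MAX_QTAL_LEN, trim_all_qtals
from .training import (
    DEFAULT_TRAIN_FRAC,
    TrainingSample,
    build_exclusions,
    build_positive_set,
    sample_negatives,
    split_train_test,
)
from .types import ExpressionMatrix, GeneModel, QTXRecord, ScoredGene, TraitOntology

logger = logging.getLogger(__name__)

# mirrors the 750-pool / 421-positive proportion of the reference design
NEGATIVE_POOL_RATIO = 750 / 421


@dataclass
class Knowledgebase:
    genes: dict[str, GeneModel]
    variants: list
    expression: ExpressionMatrix
    qtx_records: list[QTXRecord]
    ontology: TraitOntology
    trait_tissue: dict[str, str]
    chrom_sizes: dict[str, int]


def load_knowledgebase(directory: str | Path,
                       annotation_key: str = "GENEANN") -> Knowledgebase:
    """Load the five inputs from a directory laid out like the generator's."""
    d = Path(directory)
    genes = {g.gene_id: g for g in io.read_gene_models(d / "genes.gff3")}
    variants = list(io.read_variants(d / "variants.vcf", annotation_key))
    expression = io.read_expression(d / "expression.tsv", d / "samples.tsv")
    ontology = io.read_ontology(d / "ontology.tsv")
    qtx_records = io.read_qtx(d / "qtx.tsv", ontology)
    trait_tissue = io.read_trait_tissue_map(d / "trait_tissue.tsv")
    chrom_sizes = io.read_chrom_sizes(d / "chrom_sizes.tsv")
    return Knowledgebase(genes, variants, expression, qtx_records, ontology,
                         trait_tissue, chrom_sizes)


def prepare_sources(
    kb: Knowledgebase,
    min_reads: int = qc.DEFAULT_MIN_READS,
    fence_k: float = qc.DEFAULT_FENCE_K,
    beta: int = DEFAULT_BETA,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
    max_qtal_len: int = DEFAULT_MAX_QTAL_LEN,
    flank: int = DEFAULT_FLANK,
) -> FeatureSources:
    """Run QC, co-expression and QTAL trimming; bundle the feature sources."""
    cleaned, report = qc.run_qc(kb.expression, min_reads=min_reads, k=fence_k)
    logger.info("QC kept %d/%d samples", cleaned.n_samples, kb.expression.n_samples)
    filtered = filter_genes(cleaned)
    adj = adjacency(filtered, beta=beta)
    tom = topological_overlap(adj)
    modules = detect_modules(tom, filtered, min_size=min_module_size,
                             merge_threshold=merge_threshold)
    logger.info("detected %d co-expression modules", modules.n_modules)
    trimmed = trim_all_qtals(kb.qtx_records, max_len=max_qtal_len)
    return FeatureSources(
        genes=kb.genes, variants=kb.variants, expression=cleaned,
        modules=modules, qtx_records=trimmed, ontology=kb.ontology, flank=flank,
    )


@dataclass
class TrainingData:
    train: list[TrainingSample]
    test: list[TrainingSample]

    def arrays(self, which: str = "train") -> tuple[np.ndarray, np.ndarray]:
        samples = getattr(self, which)
        X = np.vstack([s.features for s in samples])
        y = np.array([s.label for s in samples])
        return X, y


def build_training_data(
    kb: Knowledgebase,
    sources: FeatureSources,
    seed: int = 0,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    n_pool: int | None = None,
) -> TrainingData:
    """Positives from QTAGs, balanced sampled negatives, features, split."""
    qtags = [q for q in kb.qtx_records if q.qtx_type == "QTAG"]
    positives = build_positive_set(qtags, kb.genes, kb.trait_tissue)
    if len(positives) < 2:
        raise ValueError(f"only {len(positives)} positive pairs; cannot train")
    traits = sorted(kb.trait_tissue)
    exclusions = build_exclusions(positives, kb.genes, sources.qtx_records,
                                  traits, kb.ontology)
    if n_pool is None:
        n_pool = int(round(NEGATIVE_POOL_RATIO * len(positives)))
    negatives = sample_negatives(
        sorted(kb.genes), traits, exclusions, n_pool=n_pool,
        n_final=len(positives), seed=seed, trait_tissue=kb.trait_tissue,
    )
    samples = positives + negatives
    triples = [(s.gene_id, s.trait, s.tissue) for s in samples]
    table = build_feature_table(triples, sources)
    for s, (_, row) in zip(samples, table.iterrows()):
        s.features = row.to_numpy()
    train, test = split_train_test(samples, train_frac=train_frac, seed=seed)
    return TrainingData(train=train, test=test)


@dataclass
class PipelineResult:
    model: FittedModel
    data: TrainingData
    train_metrics: Metrics
    test_metrics: Metrics
    ranked: list[ScoredGene] = field(default_factory=list)


def run_pipeline(
    kb: Knowledgebase,
    kind: str = "cnn",
    seed: int = 0,
    trait: str | None = None,
    candidates: list[str] | None = None,
    model_config: dict | None = None,
    **source_kwargs,
) -> PipelineResult:
    """Train one model on the knowledgebase; optionally rank candidates for
    ``trait`` (default: every gene, first trait in the map)."""
    sources = prepare_sources(kb, **source_kwargs)
    data = build_training_data(kb, sources, seed=seed)
    Xtr, ytr = data.arrays("train")
    Xte, yte = data.arrays("test")
    model = train_model(kind, Xtr, ytr, config=model_config, seed=seed,
                        fit_scaler=True)
    result = PipelineResult(
        model=model, data=data,
        train_metrics=evaluate(model, Xtr, ytr),
        test_metrics=evaluate(model, Xte, yte),
    )
    if trait is None:
        trait = sorted(kb.trait_tissue)[0]
    tissue = kb.trait_tissue[trait]
    if candidates is None:
        candidates = sorted(kb.genes)
    table = build_feature_table([(g, trait, tissue) for g in candidates], sources)
    result.ranked = prioritize(model, candidates, table.to_numpy())
    return result
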