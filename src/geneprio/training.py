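"""Balanced positive/negative training-set construction.

Positives are the experimentally supported gene-trait associations (QTAG
records), one sample per unique (gene, trait) pair. Negatives are random
(gene, trait) pairs drawn while excluding every positive pair and every
pair whose gene overlaps a same-trait QTX — a mechanized stand-in for the
manual literature screen that removed hypothetical negatives with any
published support. A larger pool is drawn first and subsampled to exactly
balance the positives.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from .qtx import count_overlaps
from .types import GeneModel, QTXRecord, TrainingSample, TraitOntology

logger = logging.getLogger(__name__)

DEFAULT_TRAIN_FRAC = 0.8
DEFAULT_NEGATIVE_POOL = 750


def resolve_qtag_gene(
    qtag: QTXRecord, genes: Mapping[str, GeneModel]
) -> str | None:
    """Resolve a QTAG interval to the gene it names: the same-chromosome gene
    with the largest overlap (ties by gene id)."""
    best, best_ov = None, 0
    for g in genes.values():
        if g.chrom != qtag.chrom:
            continue
        ov = min(g.end, qtag.end) - max(g.start, qtag.start) + 1
        if ov > best_ov or (ov == best_ov and ov > 0 and (best is None or g.gene_id < best)):
            best, best_ov = g.gene_id, ov
    return best if best_ov > 0 else None


def build_positive_set(
    qtags: Sequence[QTXRecord],
    genes: Mapping[str, GeneModel],
    trait_tissue: Mapping[str, str],
) -> list[TrainingSample]:
    """One label-1 sample per unique resolvable (gene, trait) QTAG pair."""
    seen: set[tuple[str, str]] = set()
    out: list[TrainingSample] = []
    for q in qtags:
        if q.qtx_type != "QTAG":
            continue
        gene_id = resolve_qtag_gene(q, genes)
        if gene_id is None:
            logger.warning("QTAG %s (%s:%d-%d) matches no gene; skipped",
                           q.qtx_id, q.chrom, q.start, q.end)
            continue
        pair = (gene_id, q.trait)
        if pair in seen:
            continue
        seen.add(pair)
        tissue = trait_tissue.get(q.trait)
        if tissue is None:
            logger.warning("trait %r has no mapped tissue; QTAG %s skipped",
                           q.trait, q.qtx_id)
            continue
        out.append(TrainingSample(gene_id=gene_id, trait=q.trait, tissue=tissue, label=1))
    return out


def build_exclusions(
    positives: Sequence[TrainingSample],
    genes: Mapping[str, GeneModel],
    qtx_records: Sequence[QTXRecord],
    traits: Sequence[str],
    ontology: TraitOntology | None = None,
    trait_match: str = "subcategory",
) -> set[tuple[str, str]]:
    """Pairs ineligible as negatives: positives plus any (gene, trait) whose
    gene overlaps a same-trait QTAL/QTAN."""
    excluded = {(s.gene_id, s.trait) for s in positives}
    for trait in traits:
        for g in genes.values():
            if (g.gene_id, trait) in excluded:
                continue
            for qtype in ("QTAL", "QTAN"):
                if count_overlaps(g, qtx_records, qtype, trait=trait,
                                  ontology=ontology, trait_match=trait_match) > 0:
                    excluded.add((g.gene_id, trait))
                    break
    return excluded


def sample_negatives(
    genes: Sequence[str],
    traits: Sequence[str],
    exclusions: set[tuple[str, str]],
    n_pool: int,
    n_final: int,
    seed: int,
    trait_tissue: Mapping[str, str] | None = None,
) -> list[TrainingSample]:
    """Draw ``n_pool`` eligible (gene, trait) pairs without replacement, then
    subsample ``n_final`` of them as label-0 samples."""
    if n_final > n_pool:
        raise ValueError(f"n_final {n_final} > n_pool {n_pool}")
    eligible = [(g, t) for t in traits for g in genes if (g, t) not in exclusions]
    if len(eligible) < n_pool:
        raise ValueError(
            f"only {len(eligible)} eligible (gene, trait) pairs; need n_pool={n_pool} "
            f"({len(exclusions)} pairs excluded)"
        )
    rng = np.random.default_rng(seed)
    pool_idx = rng.choice(len(eligible), size=n_pool, replace=False)
    final_idx = rng.choice(pool_idx, size=n_final, replace=False)
    out = []
    for i in sorted(final_idx):
        g, t = eligible[i]
        tissue = trait_tissue.get(t, "") if trait_tissue else ""
        out.append(TrainingSample(gene_id=g, trait=t, tissue=tissue, label=0))
    return out


def split_train_test(
    samples: Sequence[TrainingSample],
    train_frac: float = DEFAULT_TRAIN_FRAC,
    seed: int = 0,
) -> tuple[list[TrainingSample], list[TrainingSample]]:
    """Stratified split with largest-remainder rounding.

    Each class contributes floor(train_frac * n_class) training samples;
    leftover slots up to round(train_frac * n_total) go to the classes with
    the largest fractional remainders. 842 balanced samples at 0.8 therefore
    split 674/168 (337 per class in training).
    """
    if not 0 < train_frac < 1:
        raise ValueError(f"train_frac must be in (0,1), got {train_frac}")
    labels = sorted({s.label for s in samples})
    by_class = {lab: [s for s in samples if s.label == lab] for lab in labels}
    for lab, members in by_class.items():
        if len(members) < 2:
            raise ValueError(f"class {lab} has {len(members)} sample(s); need >= 2")
    targets = {lab: train_frac * len(m) for lab, m in by_class.items()}
    n_train_total = round(train_frac * len(samples))
    alloc = {lab: int(np.floor(t)) for lab, t in targets.items()}
    leftover = n_train_total - sum(alloc.values())
    order = sorted(labels, key=lambda lab: targets[lab] - alloc[lab], reverse=True)
    for lab in order[:max(0, leftover)]:
        alloc[lab] += 1
    rng = np.random.default_rng(seed)
    train: list[TrainingSample] = []
    test: list[TrainingSample] = []
    for lab in labels:
        members = list(by_class[lab])
        perm = rng.permutation(len(members))
        k = min(alloc[lab], len(members) - 1) or 1  # keep both sides nonempty
        train.extend(members[i] for i in perm[:k])
        test.extend(members[i] for i in perm[k:])
    return train, test
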