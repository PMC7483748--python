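"""QTX record processing: interval trimming, gene overlap counts, coverage.

All intervals are 1-based inclusive and overlap semantics are closed: one
shared base pair counts. Very long trait-associated loci (QTALs) reported
from low-density marker maps are trimmed to a fixed maximum length (default
2 Mb) centered on their midpoint before any overlap counting, so a single
sprawling locus cannot blanket hundreds of genes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .types import GeneModel, QTXRecord, TraitOntology

logger = logging.getLogger(__name__)

DEFAULT_MAX_QTAL_LEN = 2_000_000


def trim_qtal(record: QTXRecord, max_len: int = DEFAULT_MAX_QTAL_LEN) -> QTXRecord:
    """Trim a QTAL longer than ``max_len`` to ``max_len`` around its midpoint.

    midpoint = floor((start+end)/2); the trimmed interval is
    [midpoint - max_len//2 + 1, midpoint + (max_len - max_len//2)], which has
    length exactly ``max_len`` and the same midpoint to within 1 bp. Trimming
    that would cross position 1 is shifted right, preserving the length.
    """
    if record.qtx_type != "QTAL":
        raise ValueError(f"trim_qtal expects a QTAL, got {record.qtx_type}")
    if record.length <= max_len:
        return record
    mid = (record.start + record.end) // 2
    half = max_len // 2
    start = mid - half + 1
    end = mid + (max_len - half)
    if start < 1:
        shift = 1 - start
        start, end = 1, end + shift
    return QTXRecord(
        qtx_id=record.qtx_id,
        qtx_type=record.qtx_type,
        chrom=record.chrom,
        start=start,
        end=end,
        trait=record.trait,
        n_reports=record.n_reports,
    )


def trim_all_qtals(records: Iterable[QTXRecord],
                   max_len: int = DEFAULT_MAX_QTAL_LEN) -> list[QTXRecord]:
    return [trim_qtal(r, max_len) if r.qtx_type == "QTAL" else r for r in records]


def _traits_match(record_trait: str, query_trait: str, ontology: TraitOntology | None,
                  level: str) -> bool:
    if level == "exact" or ontology is None:
        return record_trait == query_trait
    if level == "subcategory":
        return ontology.subcategory(record_trait) == ontology.subcategory(query_trait)
    if level == "major":
        return ontology.major_category(record_trait) == ontology.major_category(query_trait)
    raise ValueError(f"unknown trait match level {level!r}")


def count_overlaps(
    gene: GeneModel,
    records: Sequence[QTXRecord],
    qtx_type: str,
    trait: str | None = None,
    ontology: TraitOntology | None = None,
    trait_match: str = "subcategory",
) -> int:
    """Count records of one type whose interval intersects the gene body.

    When ``trait`` is given, only records whose trait matches at the
    configured ontology level (``subcategory`` default, or ``major`` /
    ``exact``) are counted — gene-trait features must not pick up literature
    evidence for unrelated traits. QTALs are expected pre-trimmed.
    """
    if qtx_type not in {"QTAL", "QTAN"}:
        raise ValueError(f"count_overlaps counts QTAL or QTAN, got {qtx_type!r}")
    n = 0
    for r in records:
        if r.qtx_type != qtx_type or r.chrom != gene.chrom:
            continue
        if r.start > gene.end or r.end < gene.start:
            continue
        if trait is not None and not _traits_match(r.trait, trait, ontology, trait_match):
            continue
        n += 1
    return n


def genome_coverage(records: Sequence[QTXRecord], chrom_sizes: dict[str, int]) -> float:
    """Fraction of the genome covered by the union of record intervals."""
    total = sum(chrom_sizes.values())
    if total <= 0:
        raise ValueError("chromosome sizes sum to zero")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in records:
        if r.chrom not in chrom_sizes:
            raise ValueError(f"record {r.qtx_id} on unknown chromosome {r.chrom!r}")
        end = r.end
        if end > chrom_sizes[r.chrom]:
            logger.warning(
                "record %s extends past the end of %s; clipped", r.qtx_id, r.chrom
            )
            end = chrom_sizes[r.chrom]
        start = max(1, r.start)
        if start <= end:
            by_chrom.setdefault(r.chrom, []).append((start, end))
    covered = 0
    for intervals in by_chrom.values():
        intervals.sort()
        cur_start, cur_end = intervals[0]
        for s, e in intervals[1:]:
            if s <= cur_end + 1:
                cur_end = max(cur_end, e)
            else:
                covered += cur_end - cur_start + 1
                cur_start, cur_end = s, e
        covered += cur_end - cur_start + 1
    return covered / total
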