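"""Readers and writers for the five input table types.

GFF3/GTF goes through :mod:`gffutils`, VCF through :mod:`cyvcf2`, everything
tabular through pandas. All tabular writers emit TSV with a fixed column
order so that write -> read round-trips exactly.

Per-gene variant categories come from a configurable VCF INFO key (default
``GENEANN``) whose value is a comma-separated list of ``gene_id|category``
entries, one per annotated gene; the categories are trusted as produced by
the annotator, never recomputed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterator

import gffutils
import pandas as pd

from .types import (
    QTX_TYPES,
    STRANDS,
    VARIANT_CATEGORIES,
    ExpressionMatrix,
    GeneModel,
    QTXRecord,
    TraitOntology,
    VariantRecord,
)

logger = logging.getLogger(__name__)

GENE_TSV_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
QTX_TSV_COLUMNS = ["qtx_id", "qtx_type", "chrom", "start", "end", "trait", "n_reports"]
ONTOLOGY_TSV_COLUMNS = ["trait", "major_category", "subcategory"]


# ---------------------------------------------------------------------------
# gene models


def _validate_gff_lines(path: Path) -> None:
    """Cheap structural pass so malformed lines are reported with a number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: start/end are not integers"
                ) from None


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene features from a GFF3/GTF file or a 5-column TSV.

    The dialect is chosen by extension (``.tsv`` vs anything GFF-ish).
    Returns one :class:`GeneModel` per ``gene`` feature; coordinates are
    preserved as 1-based inclusive. Duplicate gene ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene model file not found: {path}")
    if path.suffix.lower() in {".tsv", ".txt"}:
        genes = _read_gene_models_tsv(path)
    else:
        genes = _read_gene_models_gff(path)
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def _read_gene_models_gff(path: Path) -> list[GeneModel]:
    _validate_gff_lines(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", feat.attributes.get("gene_id", [feat.id]))[0]
        if feat.strand not in STRANDS:
            raise ValueError(
                f"{path}: gene {gene_id}: strand {feat.strand!r}; "
                f"accepted values are {sorted(STRANDS)}"
            )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return genes


def _read_gene_models_tsv(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in GENE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        GeneModel(r.gene_id, str(r.chrom), int(r.start), int(r.end), r.strand)
        for r in df.itertuples(index=False)
    ]


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes],
        columns=GENE_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variants


def read_variants(
    path: str | Path, annotation_key: str = "GENEANN"
) -> Iterator[VariantRecord]:
    """Stream annotated variants from a VCF.

    Yields one record per (variant, annotated gene, alt allele). A site
    missing the annotation INFO key is emitted once per alt with
    ``category='other'`` and no gene, with a logged warning. A variant is a
    ``snp`` iff ref and alt are both single bases.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    vcf = VCF(str(path))
    for var in vcf:
        ann = var.INFO.get(annotation_key)
        entries: list[tuple[str | None, str]]
        if ann is None:
            logger.warning(
                "variant %s:%d lacks INFO/%s; emitting category 'other'",
                var.CHROM, var.POS, annotation_key,
            )
            entries = [(None, "other")]
        else:
            entries = []
            for part in str(ann).split(","):
                gene, _, cat = part.partition("|")
                cat = cat or "other"
                if cat not in VARIANT_CATEGORIES:
                    logger.warning(
                        "variant %s:%d: unknown category %r mapped to 'other'",
                        var.CHROM, var.POS, cat,
                    )
                    cat = "other"
                entries.append((gene or None, cat))
        for alt in var.ALT:
            vtype = "snp" if len(var.REF) == 1 and len(alt) == 1 else "indel"
            for gene, cat in entries:
                yield VariantRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    variant_type=vtype,
                    category=cat,
                    gene_id=gene,
                )


# ---------------------------------------------------------------------------
# expression


def read_expression(path_matrix: str | Path, path_meta: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TPM TSV plus its sample-metadata TSV.

    The matrix's first column is the gene id; metadata must cover every
    matrix sample and is re-ordered to follow the matrix columns.
    """
    values = pd.read_csv(path_matrix, sep="\t", index_col=0)
    meta = pd.read_csv(path_meta, sep="\t", index_col=0)
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples in matrix but not in metadata: {missing}")
    return ExpressionMatrix(values, meta)


def write_expression(matrix: ExpressionMatrix, path_matrix: str | Path,
                     path_meta: str | Path) -> None:
    matrix.values.to_csv(path_matrix, sep="\t", index_label="gene_id")
    matrix.meta.to_csv(path_meta, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# QTX + ontology


def read_ontology(path: str | Path) -> TraitOntology:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ONTOLOGY_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    mapping = {
        r.trait: (r.major_category, r.subcategory) for r in df.itertuples(index=False)
    }
    return TraitOntology(mapping)


def write_ontology(ontology: TraitOntology, path: str | Path) -> None:
    df = pd.DataFrame(
        [(t, mc, sc) for t, (mc, sc) in ontology.mapping.items()],
        columns=ONTOLOGY_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_qtx(path: str | Path, ontology: TraitOntology | None = None) -> list[QTXRecord]:
    """Read the QTX table.

    QTANs carrying a span are coerced to their start point (they represent
    single nucleotides). Traits absent from the ontology are logged and left
    as-is — they resolve to ``Unclassified`` at lookup time.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in QTX_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for r in df.itertuples(index=False):
        if r.qtx_type not in QTX_TYPES:
            raise ValueError(
                f"{path}: unknown qtx_type {r.qtx_type!r} for {r.qtx_id}; "
                f"accepted: {sorted(QTX_TYPES)}"
            )
        start, end = int(r.start), int(r.end)
        if r.qtx_type == "QTAN" and end != start:
            logger.warning(
                "QTAN %s has a span (%d-%d); coerced to its start point", r.qtx_id, start, end
            )
            end = start
        if ontology is not None and r.trait not in ontology:
            logger.warning(
                "trait %r of %s not in ontology; treated as Unclassified", r.trait, r.qtx_id
            )
        records.append(
            QTXRecord(r.qtx_id, r.qtx_type, str(r.chrom), start, end, r.trait,
                      int(r.n_reports))
        )
    return records


def write_qtx(records: list[QTXRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(q.qtx_id, q.qtx_type, q.chrom, q.start, q.end, q.trait, q.n_reports)
         for q in records],
        columns=QTX_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# small auxiliary tables


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                     dtype={"chrom": str})
    return dict(zip(df["chrom"], df["size"].astype(int)))


def read_trait_tissue_map(path: str | Path) -> dict[str, str]:
    """trait -> tissue map (which tissue's expression informs which trait)."""
    df = pd.read_csv(path, sep="\t")
    if not {"trait", "tissue"}.issubset(df.columns):
        raise ValueError(f"{path}: needs 'trait' and 'tissue' columns")
    return dict(zip(df["trait"], df["tissue"]))
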