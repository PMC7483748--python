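"""Synthetic multi-omics knowledgebase with planted gene-trait signal.

The generator writes the same five file types the readers consume — GFF3
gene models, an annotated VCF, a TPM matrix with sample metadata, a QTX
table and a trait ontology, plus the trait->tissue map and chromosome
sizes — and returns the ground truth of what it planted, so every stage of
the pipeline can be tested offline against known answers.

Planted structure, controlled by :class:`SimulationConfig`:

* genes laid out on a uniform grid (flank windows never collide);
* per-gene variant counts Poisson(``background_variant_rate``) in each of
  the ten (region x type) cells; genes of positive pairs get an extra
  Poisson(``nonsyn_excess``) of nonsynonymous SNPs;
* expression on the log2(TPM+1) scale: per-gene baseline + a tissue
  signature (a disjoint gene set up-shifted per tissue, which is what makes
  mislabeled samples detectable) + planted co-expression blocks driven by a
  per-sample latent factor tied to one tissue + Gaussian noise with sd
  ``expression_noise``; genes of positive pairs are up-shifted by
  ``expression_shift`` in the trait's tissue;
* QTX: one QTAG per planted pair (the positive-label source), plus
  ``qtal_excess``/``qtan_excess`` trait-matched QTALs/QTANs overlapping each
  positive gene, plus uniform background QTALs/QTANs (lengths up to 3 Mb,
  so the 2 Mb trimming rule is exercised);
* optional QC bait: samples with sub-floor mapped reads and samples whose
  profile was drawn from the wrong tissue.

Setting the four effect sizes to zero yields a null knowledgebase in which
labels carry no signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .types import COUNT_REGIONS, ExpressionMatrix, GeneModel

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 300
    n_chroms: int = 2
    chrom_len: int = 10_000_000
    gene_len: int = 4_000
    gene_spacing: int = 10_000
    n_tissues: int = 3
    samples_per_tissue: int = 10
    n_traits: int = 10
    n_positive_pairs: int = 120
    # planted effect sizes
    nonsyn_excess: float = 8.0          # extra nonsynonymous SNPs per positive gene
    expression_shift: float = 3.0       # log2 up-shift in the trait's tissue
    qtal_excess: int = 3                # trait-matched QTALs over each positive gene
    qtan_excess: int = 3                # trait-matched QTANs inside each positive gene
    # background / noise
    background_variant_rate: float = 2.0
    expression_noise: float = 0.5
    # background QTX density is scaled so each trait's QTALs cover a few
    # percent of the genome, the proportion seen in curated livestock QTL
    # collections once loci are split over trait subcategories
    n_background_qtal: int = 40
    n_background_qtan: int = 100
    long_qtal_frac: float = 0.05  # background QTALs drawn above the 2 Mb trim limit
    # co-expression blocks and tissue signatures
    n_blocks: int = 2
    block_size: int = 40
    block_tissue_assoc: float = 2.0
    signature_genes_per_tissue: int = 20
    signature_shift: float = 3.0
    # QC bait
    n_low_read_samples: int = 1
    n_mislabeled_samples: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        per_chrom = (self.chrom_len - 4 * self.gene_spacing) // self.gene_spacing
        if self.n_genes > per_chrom * self.n_chroms:
            raise ValueError("chromosomes too short for n_genes at this spacing")
        reserved = self.n_blocks * self.block_size + \
            self.n_tissues * self.signature_genes_per_tissue
        if self.n_positive_pairs > self.n_genes - reserved:
            raise ValueError(
                f"n_positive_pairs={self.n_positive_pairs} exceeds the "
                f"{self.n_genes - reserved} genes free of blocks/signatures"
            )


SMALL = SimulationConfig()
DEFAULT = SimulationConfig(
    n_genes=1000, n_chroms=3, chrom_len=10_000_000, n_tissues=5,
    samples_per_tissue=12, n_traits=20, n_positive_pairs=300,
    n_background_qtal=120, n_background_qtan=200,
)
PRESETS = {"small": SMALL, "default": DEFAULT}


def null_config(config: SimulationConfig) -> SimulationConfig:
    """The same study with every planted effect size at zero."""
    return replace(config, nonsyn_excess=0.0, expression_shift=0.0,
                   qtal_excess=0, qtan_excess=0)


@dataclass
class GroundTruth:
    positive_pairs: list[tuple[str, str]]
    trait_tissue: dict[str, str]
    module_genes: dict[int, list[str]]
    variant_counts: dict[str, dict[str, int]]   # gene -> feature name -> count
    planted_qtal: dict[tuple[str, str], int]
    planted_qtan: dict[tuple[str, str], int]
    mislabeled_samples: list[str]
    low_read_samples: list[str]
    genes: dict[str, GeneModel] = field(default_factory=dict)


def _layout_genes(cfg: SimulationConfig) -> list[GeneModel]:
    genes = []
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    i = 0
    for c in range(1, cfg.n_chroms + 1):
        for j in range(per_chrom):
            if i >= cfg.n_genes:
                break
            start = 3_001 + j * cfg.gene_spacing
            genes.append(GeneModel(
                gene_id=f"G{i + 1:04d}", chrom=str(c), start=start,
                end=start + cfg.gene_len - 1, strand="+" if i % 2 == 0 else "-",
            ))
            i += 1
    return genes


def _region_range(gene: GeneModel, region: str, flank: int = 2_000) -> tuple[int, int]:
    left = (gene.start - flank, gene.start - 1)
    right = (gene.end + 1, gene.end + flank)
    if region == "upstream":
        return left if gene.strand == "+" else right
    if region == "downstream":
        return right if gene.strand == "+" else left
    return gene.start, gene.end  # genic categories


def simulate_knowledgebase(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Write the knowledgebase files under ``out_dir``; return paths + truth."""
    cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genes = _layout_genes(cfg)
    gene_ids = [g.gene_id for g in genes]
    gene_by_id = {g.gene_id: g for g in genes}
    tissues = [f"tissue_{t + 1}" for t in range(cfg.n_tissues)]
    traits = [f"trait_{t + 1}" for t in range(cfg.n_traits)]
    trait_tissue = {tr: tissues[i % cfg.n_tissues] for i, tr in enumerate(traits)}

    # --- partition genes: blocks | tissue signatures | free pool -----------
    perm = rng.permutation(cfg.n_genes)
    cursor = 0
    module_genes: dict[int, list[str]] = {}
    for b in range(cfg.n_blocks):
        module_genes[b + 1] = [gene_ids[i] for i in perm[cursor:cursor + cfg.block_size]]
        cursor += cfg.block_size
    signature: dict[str, list[str]] = {}
    for t in tissues:
        signature[t] = [gene_ids[i]
                        for i in perm[cursor:cursor + cfg.signature_genes_per_tissue]]
        cursor += cfg.signature_genes_per_tissue
    free = [gene_ids[i] for i in perm[cursor:]]

    # --- positive pairs: distinct free genes, traits round-robin -----------
    pos_genes = list(rng.choice(free, size=cfg.n_positive_pairs, replace=False))
    positive_pairs = [(g, traits[i % cfg.n_traits]) for i, g in enumerate(pos_genes)]

    # --- gene models --------------------------------------------------------
    gff_path = out / "genes.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in range(1, cfg.n_chroms + 1):
            fh.write(f"##sequence-region {c} 1 {cfg.chrom_len}\n")
        for g in genes:
            fh.write(f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")

    sizes_path = out / "chrom_sizes.tsv"
    with open(sizes_path, "w") as fh:
        for c in range(1, cfg.n_chroms + 1):
            fh.write(f"{c}\t{cfg.chrom_len}\n")

    # --- variants ------------------------------------------------------------
    pos_gene_set = {g for g, _ in positive_pairs}
    variant_counts: dict[str, dict[str, int]] = {}
    vcf_rows: list[tuple[str, int, str, str, str]] = []
    for g in genes:
        counts: dict[str, int] = {}
        for region in COUNT_REGIONS:
            lo, hi = _region_range(g, region)
            span = np.arange(lo, hi + 1)
            for vtype in ("snp", "indel"):
                lam = cfg.background_variant_rate
                if (region == "nonsynonymous" and vtype == "snp"
                        and g.gene_id in pos_gene_set):
                    lam += cfg.nonsyn_excess
                k = min(int(rng.poisson(lam)), len(span))
                counts[f"{region.capitalize()}_{vtype}"] = k
                if k == 0:
                    continue
                positions = np.sort(rng.choice(span, size=k, replace=False))
                for pos in positions:
                    ref = _BASES[rng.integers(4)]
                    if vtype == "snp":
                        alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
                    else:
                        ref, alt = ref + _BASES[rng.integers(4)], ref
                    vcf_rows.append((g.chrom, int(pos), ref, alt,
                                     f"GENEANN={g.gene_id}|{region}"))
        variant_counts[g.gene_id] = counts

    vcf_rows.sort(key=lambda r: (r[0], r[1]))
    vcf_path = out / "variants.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in range(1, cfg.n_chroms + 1):
            fh.write(f"##contig=<ID={c},length={cfg.chrom_len}>\n")
        fh.write('##INFO=<ID=GENEANN,Number=.,Type=String,'
                 'Description="gene_id|category annotations">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, info in vcf_rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")

    # --- expression ----------------------------------------------------------
    sample_ids, sample_tissue = [], []
    for t in tissues:
        for r in range(cfg.samples_per_tissue):
            sample_ids.append(f"{t}_s{r + 1}")
            sample_tissue.append(t)
    n_samples = len(sample_ids)

    # mislabeled samples keep their label but express another tissue's profile
    mislabeled = []
    profile_tissue = list(sample_tissue)
    if cfg.n_mislabeled_samples and cfg.n_tissues > 1:
        chosen = rng.choice(n_samples, size=cfg.n_mislabeled_samples, replace=False)
        for idx in chosen:
            others = [t for t in tissues if t != sample_tissue[idx]]
            profile_tissue[idx] = others[rng.integers(len(others))]
            mislabeled.append(sample_ids[idx])

    base = rng.uniform(1.0, 6.0, size=cfg.n_genes)
    X = np.tile(base[:, None], (1, n_samples))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for t in tissues:
        rows = [gene_index[g] for g in signature[t]]
        cols = [j for j in range(n_samples) if profile_tissue[j] == t]
        X[np.ix_(rows, cols)] += cfg.signature_shift
    for b, members in module_genes.items():
        tied = tissues[(b - 1) % cfg.n_tissues]
        factor = (cfg.block_tissue_assoc
                  * np.array([profile_tissue[j] == tied for j in range(n_samples)], float)
                  + rng.normal(0, 1, size=n_samples))
        rows = [gene_index[g] for g in members]
        loadings = rng.uniform(0.8, 1.2, size=len(rows))
        X[rows] += loadings[:, None] * factor[None, :]
    for g, trait in positive_pairs:
        cols = [j for j in range(n_samples) if profile_tissue[j] == trait_tissue[trait]]
        X[gene_index[g], cols] += cfg.expression_shift
    X += rng.normal(0, cfg.expression_noise, size=X.shape)
    tpm = np.round(np.clip(2.0**X - 1.0, 0.0, None), 4)

    mapped = rng.integers(8_000_000, 40_000_000, size=n_samples)
    low_read = []
    if cfg.n_low_read_samples:
        eligible = [j for j in range(n_samples) if sample_ids[j] not in mislabeled]
        chosen = rng.choice(eligible, size=cfg.n_low_read_samples, replace=False)
        for idx in chosen:
            mapped[idx] = int(rng.integers(1_000_000, 5_000_000))
            low_read.append(sample_ids[idx])

    expr_path, meta_path = out / "expression.tsv", out / "samples.tsv"
    pd.DataFrame(tpm, index=pd.Index(gene_ids, name="gene_id"),
                 columns=sample_ids).to_csv(expr_path, sep="\t")
    pd.DataFrame({"sample_id": sample_ids, "tissue": sample_tissue,
                  "mapped_reads": mapped}).to_csv(meta_path, sep="\t", index=False)

    # --- QTX table -----------------------------------------------------------
    qtx_rows = []
    qid = 0

    def add(qtype: str, chrom: str, start: int, end: int, trait: str) -> None:
        nonlocal qid
        qid += 1
        qtx_rows.append((f"Q{qid:05d}", qtype, chrom, start, end, trait,
                         int(rng.integers(1, 30))))

    planted_qtal: dict[tuple[str, str], int] = {}
    planted_qtan: dict[tuple[str, str], int] = {}
    for g_id, trait in positive_pairs:
        g = gene_by_id[g_id]
        add("QTAG", g.chrom, g.start, g.end, trait)
        for _ in range(cfg.qtal_excess):
            s = max(1, g.start - int(rng.integers(0, 50_000)))
            e = min(cfg.chrom_len, g.end + int(rng.integers(0, 50_000)))
            add("QTAL", g.chrom, s, e, trait)
        for _ in range(cfg.qtan_excess):
            p = int(rng.integers(g.start, g.end + 1))
            add("QTAN", g.chrom, p, p, trait)
        planted_qtal[(g_id, trait)] = cfg.qtal_excess
        planted_qtan[(g_id, trait)] = cfg.qtan_excess
    for _ in range(cfg.n_background_qtal):
        chrom = str(rng.integers(1, cfg.n_chroms + 1))
        if rng.random() < cfg.long_qtal_frac:  # sprawling loci the trim rule catches
            length = int(rng.integers(2_000_001, 3_000_000))
        else:
            length = int(rng.integers(20_000, 200_000))
        s = int(rng.integers(1, max(2, cfg.chrom_len - 20_000)))
        add("QTAL", chrom, s, min(cfg.chrom_len, s + length - 1),
            traits[rng.integers(cfg.n_traits)])
    for _ in range(cfg.n_background_qtan):
        chrom = str(rng.integers(1, cfg.n_chroms + 1))
        p = int(rng.integers(1, cfg.chrom_len + 1))
        add("QTAN", chrom, p, p, traits[rng.integers(cfg.n_traits)])

    qtx_path = out / "qtx.tsv"
    pd.DataFrame(qtx_rows, columns=["qtx_id", "qtx_type", "chrom", "start", "end",
                                    "trait", "n_reports"]).to_csv(
        qtx_path, sep="\t", index=False)

    # --- ontology + trait->tissue map ---------------------------------------
    onto_path = out / "ontology.tsv"
    pd.DataFrame(
        [(tr, f"major_{(i % 3) + 1}", f"sub_{tr}") for i, tr in enumerate(traits)],
        columns=["trait", "major_category", "subcategory"],
    ).to_csv(onto_path, sep="\t", index=False)
    map_path = out / "trait_tissue.tsv"
    pd.DataFrame(sorted(trait_tissue.items()), columns=["trait", "tissue"]).to_csv(
        map_path, sep="\t", index=False)

    paths = {
        "genes": gff_path, "variants": vcf_path, "expression": expr_path,
        "samples": meta_path, "qtx": qtx_path, "ontology": onto_path,
        "trait_tissue": map_path, "chrom_sizes": sizes_path,
    }
    truth = GroundTruth(
        positive_pairs=positive_pairs, trait_tissue=trait_tissue,
        module_genes=module_genes, variant_counts=variant_counts,
        planted_qtal=planted_qtal, planted_qtan=planted_qtan,
        mislabeled_samples=mislabeled, low_read_samples=low_read,
        genes=gene_by_id,
    )
    return paths, truth


# ---------------------------------------------------------------------------
# direct labeled-feature generator for model tests


def simulate_labeled_features(
    n: int, weights: np.ndarray, intercept: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Raw 14-feature matrix and labels from a known logistic model.

    Features follow the supports of the real pipeline: Poisson counts for
    the ten variant cells and the two QTX counts, a nonnegative gamma for
    Expression, uniform [-1, 1] for Module. Labels are Bernoulli with
    success probability logistic(w . x_std + b) on the z-scored features.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (14,):
        raise ValueError(f"need 14 weights, got shape {weights.shape}")
    rng = np.random.default_rng(seed)
    X = np.empty((n, 14))
    X[:, :10] = rng.poisson(3.0, size=(n, 10))
    X[:, 10] = rng.gamma(shape=2.0, scale=1.5, size=n)
    X[:, 11] = rng.uniform(-1.0, 1.0, size=n)
    X[:, 12:14] = rng.poisson(2.0, size=(n, 2))
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xstd = (X - mu) / sd
    logits = Xstd @ weights + intercept
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
    return X, y, {"weights": weights, "intercept": intercept}


def simulate_block_expression(
    n_per_block: int = 40,
    n_blocks: int = 2,
    n_background: int = 0,
    n_samples: int = 30,
    noise: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Expression with planted co-expression blocks; returns matrix + labels
    (block index per gene, 0 for background genes)."""
    rng = np.random.default_rng(seed)
    n_genes = n_blocks * n_per_block + n_background
    labels = np.concatenate([
        np.repeat(np.arange(1, n_blocks + 1), n_per_block),
        np.zeros(n_background, dtype=int),
    ])
    base = rng.uniform(1.0, 6.0, size=n_genes)
    X = np.tile(base[:, None], (1, n_samples))
    for b in range(1, n_blocks + 1):
        factor = rng.normal(0, 1, size=n_samples)
        rows = np.flatnonzero(labels == b)
        loadings = rng.uniform(0.8, 1.2, size=len(rows))
        X[rows] += loadings[:, None] * factor[None, :]
    X += rng.normal(0, noise, size=X.shape)
    tpm = np.clip(2.0**X - 1.0, 0.0, None)
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    sample_ids = [f"s{j + 1}" for j in range(n_samples)]
    values = pd.DataFrame(tpm, index=pd.Index(gene_ids, name="gene_id"),
                          columns=sample_ids)
    meta = pd.DataFrame({"tissue": ["t1"] * n_samples,
                         "mapped_reads": [10_000_000] * n_samples},
                        index=pd.Index(sample_ids, name="sample_id"))
    return ExpressionMatrix(values, meta), labels
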