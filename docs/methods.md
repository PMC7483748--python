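# Methods

This note documents the models, conventions and design choices behind
`geneprio`, in the order the pipeline runs them.

## Coordinate and format conventions

All coordinates are 1-based inclusive (GFF/VCF convention); overlap of
closed intervals counts a single shared base pair. Gene models come from
GFF3/GTF (or a 5-column TSV), variants from VCF 4.x with a configurable
INFO key (default `GENEANN`, value `gene_id|category[,gene_id|category…]`)
carrying per-gene functional categories. Categories are trusted as produced
by the upstream annotator and never recomputed — annotation is an input,
not a pipeline stage. A variant is a SNP iff ref and alt are single bases;
multi-allelic sites expand to one record per alt. QTAN records represent
single nucleotides; any span in the input is coerced to the start position
with a warning. Traits missing from the ontology map to `Unclassified`
rather than erroring, so partial ontologies keep pipelines runnable.

## Expression QC

Two passes, applied once (no iterative re-fencing):

1. **Mapped-read floor.** Samples with fewer than 6,000,000 mapped reads
   are removed (strict `<`; a sample at exactly the floor is kept).
2. **Tissue-outlier removal.** Within each tissue, pairwise Euclidean
   distances between sample profiles are computed on log2(TPM+1) — raw TPM
   would let a handful of highly expressed genes dominate the metric. Each
   sample is summarized by its *mean* distance to its same-tissue peers
   (configurable to median; some reduction of the pairwise distances to a
   per-sample statistic is required and the mean is the simplest symmetric
   choice). Samples whose summary falls outside Tukey's fences
   [Q1 − k·IQR, Q3 + k·IQR] with k = 3 (the far-outlier setting) are
   removed. Quartiles use linear interpolation between order statistics
   (the common "type 7" rule); the convention is fixed and documented
   because fence positions depend on it. Tissues with fewer than 4 samples
   pass through untouched with a warning — quartiles of 3 values are not
   meaningful.

## Co-expression network

Adjacency is `a_ij = |cor(x_i, x_j)|^β` on log2(TPM+1) profiles, with soft
power β = 6 by default (the customary unsigned-network default; results of
module detection are convention-dependent and β is exposed). From it the
unsigned topological overlap

    tom_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

with connectivity `k_i = Σ_{u≠i} a_iu` measures shared network
neighborhood. Modules are detected by average-linkage hierarchical
clustering of `1 − TOM`, a **static** cut at 0.99 of the maximum merge
height (dynamic tree cutting is a possible future refinement; the static
cut is dependency-free and easy to reason about), a minimum module size of
30, and a merge step that greedily joins module pairs whose eigengene
correlation is at least 1 − 0.2. The eigengene is the first principal
component score vector (via SVD) of the module's per-gene standardized
expression, with its sign fixed so it correlates positively with the module
mean profile — PCA is sign-ambiguous and the feature downstream is a signed
correlation. Genes with zero variance or more than 50% missing values are
filtered first. The Module feature of a (gene, tissue) pair is the Pearson
correlation between the gene's module eigengene and the binary
tissue-membership indicator over samples; unassigned genes get 0 (a neutral
value), as do modules when the indicator is constant.

On realistic mixed data the static cut tends to produce one large
tissue-driven module rather than many small ones; the planted-block
recovery study isolates the clustering itself and recovers clean blocks
exactly (Rand index 1.0 across seeds).

## QTX processing

QTALs longer than 2 Mb — typically artifacts of sparse marker maps — are
trimmed to exactly 2 Mb centered on their midpoint
(`mid = ⌊(start+end)/2⌋`, window `[mid − 1 Mb + 1, mid + 1 Mb]`) before any
overlap counting. Edge clipping preserves the trimmed length rather than
the center so feature counts stay comparable across genes (for 1-based
records the clip can in fact never trigger; the guard is defensive).
Gene–QTX overlap features are counted per qtx type against the gene body
with closed-interval semantics, restricted to records whose trait matches
the query trait at the **subcategory** level of the ontology (configurable
to major-category or exact matching) — literature evidence for unrelated
traits must not leak into a gene–trait feature. Genome coverage is the
union length of record intervals over the genome size.

## Feature vector

The 14 features, in fixed order (the order is part of the model artifact):
`Upstream_snp, Downstream_snp, Intron_snp, Synonymous_snp,
Nonsynonymous_snp, Upstream_indel, Downstream_indel, Intron_indel,
Synonymous_indel, Nonsynonymous_indel, Expression, Module, QTAL, QTAN`.

Flanks are 2 kb and strand-aware: upstream of a minus-strand gene lies at
higher coordinates. The flank *side* is recomputed from position and
strand; genic categories are taken from the annotation and required to fall
inside the gene body. Exonic variation is represented solely by the
synonymous/nonsynonymous split. Expression is the mean log2(TPM+1) in the
target tissue (log scale; raw TPM would make the feature heavy-tailed).

Counts and correlations live on very different scales, so features are
z-scored (population sd) before model fitting. Scaler parameters are
learned on training data only and serialized with the model; candidates
are always scored in the training frame. Zero-variance columns pass
through unscaled and are flagged.

## Training set

Positives: one label-1 sample per unique (gene, trait) QTAG pair, the gene
resolved as the maximal-overlap gene model of the QTAG interval. Negatives:
random (gene, trait) pairs drawn without replacement from a pool
(≈ 750/421 ≈ 1.8× the positive count, mirroring the reference proportions),
excluding every positive pair and every pair whose gene overlaps any
same-subcategory QTAL/QTAN — a mechanized stand-in for a manual literature
screen of hypothetical negatives; it is an approximation and is documented
as such. The pool is then subsampled to exactly balance the positives.
Each sample's tissue comes from a user-supplied trait→tissue map.

The 80/20 split is stratified by label with largest-remainder rounding:
each class contributes ⌊0.8·n_c⌋ training samples and leftover slots up to
round(0.8·n) go to the largest fractional remainders — 842 balanced
samples therefore split 674/168, 337 positives and negatives each in
training.

## Classifiers and scoring

* `lr` — unpenalized logistic regression (Newton-CG).
* `svc` — linear SVC, squared hinge, C = 0.1, L2, tol 1e-5. The class
  decision is the signum of the margin, which cannot rank; for scoring the
  margin is mapped through a logistic and scaled to 0–100. This is an
  artifact decision: any strictly monotone map of the margin gives the
  same ranking.
* `mlp` — two hidden layers of 8 tanh units, L-BFGS, tol 1e-5, ≤ 60
  iterations.
* `cnn` — a 1D convnet implemented in numpy (no deep-learning framework
  dependency): four conv blocks (filters 32/64/128/256, kernel 3, stride 1,
  same padding, ReLU, L1(0.001) on kernels) each followed by max pooling
  (size 2, stride 2, same padding), then dense 1024- and 512-unit ReLU
  layers each followed by dropout (rate 0.5, configurable), and a two-way
  softmax. For input length 14 the spatial length contracts 14→7→4→2→1, so
  the flattened width is 256 (asserted at construction). Training:
  cross-entropy plus the L1 penalty, Adam at 1e-3, batches of 32, up to 200
  epochs with early stopping (patience 10) on a 10% stratified validation
  split, restoring the best weights. The early-stopping monitor is the
  validation data term *without* the L1 penalty: the penalty decreases
  monotonically as weights shrink and would otherwise mask rising
  validation error. All randomness flows through one seeded generator, so
  training is bit-for-bit reproducible.

`Score(g) = 100·e^{z₂}/(e^{z₁}+e^{z₂})`, computed in the overflow-safe
logistic form; for the two-class case it coincides with 100·P(Y=1|x).
Credible means strictly `score > 50`; ties at exactly 50 are non-credible.
Rank ties break lexicographically by gene id — determinism over aesthetics.

Cross-validation is stratified k-fold (default 4) over a small setting
grid; each fold re-fits its own scaler so no test information leaks into
scaling. Evaluation reports accuracy, precision, recall and F1 with the
credible class positive and zero-division mapped to 0. Group comparisons
(top/bottom credible vs top non-credible) use the two-sided Mann–Whitney
test: exact enumeration when both groups have ≤ 8 tie-free values, else
the tie-corrected normal approximation.

## Explanation

`explain` fits a local linear surrogate: perturbations drawn per-feature
from a normal with the background's mean and sd, weighted by
exp(−d²/w²) on standardized distance to the instance (kernel width
0.75·√d), and a weighted ridge regression of the model's scores in the
standardized frame. `aggregate_importance` is the mean |surrogate weight|
per feature across instances, normalized so the maximum is 100%.

## Enrichment

Upper-tail hypergeometric P = Pr(X ≥ m), evaluated through scipy's
log-space survival function. The background is the set of genes with at
least one annotation; terms annotating no background gene are untestable
and are excluded from the Bonferroni multiplier. Corrected
P = min(1, P·#terms); significance at corrected P ≤ 0.05. Annotation input
is a flat two-column (gene, term) TSV; ontology-graph propagation is out of
scope.

## Synthetic knowledgebase

The generator writes exactly the files the readers consume (dogfooding
guarantees format compatibility) and records its ground truth. The small
preset: 300 genes on a 10 kb grid over two 10 Mb chromosomes, 3 tissues ×
10 samples, 10 traits mapped round-robin to tissues, 120 planted positive
(gene, trait) pairs. Generative families are the simplest consistent with
each feature's support: Poisson(2) variant counts per (region × type) cell
with positives receiving Poisson(2+8) nonsynonymous SNPs; log-normal-style
expression (Gaussian on the log2 scale, sd 0.5) with per-tissue signature
gene sets (+3), two planted 40-gene co-expression blocks driven by a
per-sample latent factor, and a +3 shift for positive genes in their
trait's tissue; per positive pair, 3 trait-matched QTALs and 3 QTANs over
the gene plus one QTAG (the label source). Background QTX density is
scaled to the per-subcategory coverage seen in curated livestock QTL
collections (a few percent of the genome per trait subcategory): 40
background QTALs of 20–200 kb, 5% drawn above 2 Mb so trimming is
exercised, and 100 background QTANs. One sample with sub-floor mapped
reads and one expressing the wrong tissue's profile are planted as QC
bait. Setting the four effect sizes to zero yields a null knowledgebase
whose labels carry no feature signal.

What the generator does **not** emulate: linkage disequilibrium, gene
density gradients, read-level noise, batch effects, correlated trait
ontologies, or label noise in the positives. Passing tests therefore show
that the method recovers the statistical structure it assumes, at desk
scale — not that it reproduces performance on real terabyte-scale
compendia, whose headline numbers depend on curated training data this
package does not ship.

## Problem sizes and determinism

The default test and reproduction runs use the small preset
(300 genes, 30 samples, 240 training pairs), 10 seeds × n = 2000 for
weight-sign recovery, and 10 seeds of the 80-gene block study — sizes
chosen so the whole suite runs in minutes on one CPU while every check
retains a comfortable signal margin. All stochastic steps take explicit
seeds; linear and MLP paths are exactly reproducible, the CNN bit-for-bit
under a fixed seed (the documented tolerance for cross-platform BLAS
variation is 1e-3 on scores).

## Known limitations

* The static tree cut merges tissue-correlated genes into broad modules on
  realistic data; dynamic tree cutting would refine this.
* The negative-screen proxy (same-subcategory QTX overlap) is weaker than
  a manual literature review; a small fraction of sampled negatives may be
  unrecognized true associations in real data.
* The CNN, with ~0.8 M parameters on 14 inputs, only pays off over the
  linear models when feature interactions matter; on small noisy training
  sets early stopping on a small validation split is the dominant variance
  source.
* Scores are softmax outputs, not calibrated probabilities.
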