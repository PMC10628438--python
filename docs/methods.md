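# Methods

## Representative cells

Single-cell matrices are sparse and tall; correlating genes across tens of
thousands of individual cells is both noisy and expensive. Each cell group
(any categorical metadata column; typically cell type) is therefore
partitioned into N sub-clusters and each sub-cluster is collapsed to one
representative cell by per-gene arithmetic mean.

Sub-clustering is k-means (k = N, k-means++ init, 10 restarts, fixed seed)
on the top principal components (default 50, capped at min(cells − 1,
genes)) of the group's z-scored expression. k-means on a PCA embedding was
chosen because it is deterministic under a seed and cheap; graph-based
metacell construction is out of scope. If k-means returns an empty cluster
the group is re-seeded up to 5 times before erroring. Groups with fewer
than N cells are dropped (with a warning) rather than clustered at lower
k, so every retained group contributes exactly N representative cells and
groups stay balanced in the network stage. N has no default: a good value
depends on group sizes and sequencing depth, and must be chosen by the
user.

Averaging is performed on whatever scale the input is on; the pipeline
default first applies library-size normalization (counts per 10⁴) and
log1p. Averaging conserves mass exactly: the size-weighted sum of
representative values equals the per-gene sum over the original cells
(checked to 1e-9 relative tolerance in the tests).

## Co-expression network and modules

**Correlation.** Default is the biweight midcorrelation: with
u_i = (x_i − med(x)) / (9·mad(x)) (mad unscaled) and weights
w_i = (1 − u_i²)²·1[|u_i| < 1], each vector is replaced by
(x_i − med(x))·w_i and correlated as a cosine. It down-weights outlier
samples, which matters because representative cells are few. Genes with
mad = 0 fall back to a Pearson-standardized vector for their pairs.
Pearson and Spearman are available; trait association uses Spearman.

**Adjacency.** Signed network by default: a_ij = ((1 + cor_ij)/2)^β, which
maps anti-correlation near 0 instead of conflating it with positive
co-expression. β is selected as the smallest integer in 1..20 whose
connectivity distribution passes the scale-free fit (signed R² ≥ 0.85:
OLS of log10 p(k) on log10 k over 10 equal-width connectivity bins, R²
multiplied by −sign(slope)). When no power passes — common at small sample
counts, where correlations are inflated — the best-fitting power is used
and flagged. Connectivity always excludes the self term.

**TOM and clustering.** Topological overlap
TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij),
TOM_ii = 1. Genes are clustered by average linkage on 1 − TOM with a
static cut at 0.995 of the tree height; branches below the minimum module
size (default 30) become the unassigned "grey" pool (label 0). Modules
whose eigengenes correlate ≥ 1 − merge_cut (default 0.25) are merged
iteratively, closest pair first, and labels are renumbered 1..M by
decreasing size. The static cut is a deliberate simplification of dynamic
hybrid tree cutting: it is fully deterministic and easy to reason about in
tests; its main cost is that large loosely-coherent background branches
can survive as a module instead of being dispersed, and nearby planted
modules occasionally merge. Both effects are visible in the synthetic
benchmark and bounded by the ARI check.

**Eigengenes, kIM, kME, hubs.** A module's eigengene is the first
principal-component score vector of its z-scored expression, unit-norm,
sign-oriented so the mean correlation with member genes is non-negative;
var_explained is the leading eigenvalue fraction. Single-gene modules use
the gene's z-score. kIM_i is the summed adjacency to same-module partners;
kME_i is the correlation (network flavor) of gene i with its own module's
eigengene. Hubs are the intersection of the top ⌈0.10·m⌉ genes by kIM and
by kME, ties broken lexicographically for determinism.

**Trait association.** Categorical metadata columns are expanded to
one-hot indicators; numeric columns used directly. Each (module, trait)
cell is a Spearman correlation with its asymptotic p-value,
Benjamini–Hochberg adjusted across the whole matrix. Constant traits are
reported as ρ = 0 with a flag rather than NaN.

## Regulatory network

TF scanning is an exact-symbol intersection of the module's genes with a
user-supplied TF list. Each target gene is regressed on all module TFs
(excluding itself) with stochastic gradient-boosted trees: up to 500
trees, learning rate 0.01, 90% subsampling, sqrt feature fraction, and
early stopping when the mean out-of-bag improvement over the last 25
rounds is non-positive. A TF's importance for a target is its total
impurity-reduction (gain) summed over all splits across trees — the
unnormalized gain, so importances are comparable across targets. Edges
with positive gain become candidates, capped by default at the 50
strongest per TF before motif testing; the cap keeps the enrichment sets
bounded and is configurable.

Motif validation follows the ranking-and-recovery convention: for a TF's
candidate target set S and each motif's genome-wide ranking, the recovery
AUC is Σ_{r=1..T} c(r)/(T·|S|) with c(r) the number of members at rank ≤ r
and T = ⌈0.05·G⌉. The NES of a motif is its AUC standardized against the
AUC distribution of *all* motifs in the database for that same set. Motifs
annotated to the TF with NES ≥ 3.0 are enriched; an edge survives iff its
target is in the leading edge (rank ≤ T) of at least one enriched motif,
and the best-NES supporting motif is attached to the edge. TFs with no
motif annotation lose all their edges by default (flagged in the report);
`keep_unannotated` passes them through marked as unsupported. The 5% rank
threshold and NES ≥ 3 follow the established cisTarget-style convention.

## Drug overlay

Mapping is an exact gene-symbol join against a local drug-target TSV
snapshot; the file's provenance string (its leading comment line) is
echoed into every output so results are attributable to a pinned table.
No interactome expansion or identifier translation is performed — live,
weekly-updated drug databases are deliberately replaced by the versioned
snapshot for reproducibility. The combined graph types nodes as
gene / tf / drug (drug ids prefixed with `drug:` to avoid symbol
collisions), keeps TF→target edges directed, and stores drug-gene and
co-expression links as reciprocal directed edges for clean GraphML export.

## Synthetic ground truth

The generator emulates the data the pipeline expects: counts are negative
binomial (gamma-Poisson, dispersion 0.5) with per-gene baseline log-means
uniform in [0.5, 3.0]. Five planted modules of 60 genes (default; 1000
genes, 2 groups × 300 cells) each follow a latent per-cell activity
z_m ~ Normal(shift, 1), where the shift is specific to the cell's
(group, blob) sub-population and itself drawn Normal(0, 1) — the blob
structure gives the representative-cell step a recoverable truth and
gives module activities between-representative-cell variance. Module
member genes add 0.8·z_m to their log-mean; each module's designated
driver TF uses loading 1.0. The blob-shift scale of 1.0 (one unit of
log-mean spread across sub-populations) was fixed once as a realistic
cell-state effect size.

The motif database plants, per driver TF, one true motif whose ranking
holds 90% of the TF's regulon uniformly within the top 5% of ranks (the
placed count is capped at the size of the top region, which the default
regulon slightly exceeds — the cap is the maximal physically possible
enrichment), plus two annotated decoy motifs and unannotated background
motifs with uniformly random rankings. The drug table assigns each of 30
drugs 1–3 uniformly sampled target genes.

What the generator does *not* emulate: dropout-specific zero inflation,
batch effects, doublets, ambient RNA, or realistic gene-gene correlation
beyond the module factors. Passing the synthetic benchmarks therefore
demonstrates the algorithms recover planted structure under NB noise, not
performance on any particular real dataset.

## Problem sizes and numerics

The test suite and the acceptance script run the default scenario
(600 × 1000, 5 modules), a 20-seed linear-regulation benchmark
(200 samples, 10 TFs, 10 targets), and 20 motif-database replicates —
sizes chosen so planted effects are comfortably detectable while the whole
suite stays fast on one CPU. Numerical conventions: correlations are
clipped to [−1, 1] and symmetrized; TOM is clipped to [0, 1] with unit
diagonal; eigengene signs are fixed by the mean-member-correlation rule;
hub and edge orderings break ties lexicographically; all stochastic steps
take explicit seeds and per-group k-means seeds are derived
deterministically from the caller's seed.

## Known limitations

- The static tree cut (vs dynamic hybrid cutting) can leave a large
  background branch as a module; interpret the largest module with care
  on weakly structured data.
- Soft-threshold selection at very small sample counts (e.g. 20
  representative cells) rarely passes the R² cut; the flagged best-power
  fallback is then used.
- Motif enrichment assumes the database's gene universe covers the
  candidate targets; missing genes are dropped with a warning rather than
  re-normalized.
- The drug overlay is a symbol join: no orthology, aliasing, or
  interactome neighborhood expansion.
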