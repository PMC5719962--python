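# Methods

This note documents the models and numerical choices behind each stage of
the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Input model and filtering

The pipeline operates on a genes × samples matrix of non-negative
normalized expression values (FPKM-like units). Missing entries
(non-numeric cells in the TSV) are distinguished from observed zeros: a
zero is evidence of non-expression, a missing cell is no evidence at all.

Two filters precede network construction:

* **Presence filter.** A gene is kept when it is expressed — non-missing
  and strictly positive — in strictly more than `min_expressed_samples`
  samples. The convention for a 92-sample atlas is a threshold of half
  the samples (46), i.e. genes expressed in 46 or fewer tissues are
  treated as non-informative. Expression exactly 0 does not count as
  presence; no positivity floor above 0 is applied.
* **MAD selection.** Per-gene variability is the median absolute
  deviation, MAD = median(|x − median(x)|), over non-missing values. The
  1.4826 normal-consistency constant is deliberately omitted: only the
  ranking matters for selection and a constant factor cancels. Genes with
  fewer than two non-missing values get MAD 0 (logged, not an error).
  Ties at the `top_n` boundary break by ascending gene identifier so the
  selected set is identical across platforms. Both filters preserve the
  input row order.

## Biweight midcorrelation

Similarity between genes is the biweight midcorrelation: with
u_i = (x_i − med x) / (9 · MAD x), sample weights are
w_i = (1 − u_i²)² for |u_i| < 1 and 0 beyond, and the weighted,
median-centered vectors are correlated. Samples more than 9 MADs from the
median therefore contribute nothing, which bounds the influence of a
single aberrant tissue. No cap on the proportion of downweighted samples
is applied. Missing samples get weight zero on both sides of a pair.

Genes with MAD 0 (more than half their values identical) have no defined
weighting envelope; every pair involving such a gene falls back to
Pearson correlation (logged). Genes with zero variance have no defined
correlation at all and get similarity 0, including on the diagonal.

## Soft threshold and the scale-free criterion

Adjacency is unsigned: a_ij = |S_ij|^β with zero diagonal (self-similarity
is not a connection, so connectivity k_i = Σ_j a_ij excludes it). The
power β is selected by scanning an integer grid (default 1..20): for each
candidate, connectivity is binned into 10 equal-width bins and
log10(frequency) is regressed on log10(mean k) over non-empty bins. The
fit index is R² signed negative when the regression slope is positive, so
only decaying distributions can pass the cutoff (default 0.8). The chosen
β is the smallest passing candidate; if none passes, the best-fitting
candidate is chosen with a warning. Because |S| ≤ 1, per-gene connectivity
is non-increasing in β, which the scan reports alongside mean, median and
maximum connectivity.

Two distinct exponents are conventionally both written β in this
literature: the soft-threshold power and the fitted degree-distribution
exponent. Here "beta" always means the soft power; the degree exponent is
reported as `powerlaw_exponent` (the negated regression slope, positive
for decaying distributions) and uses the same 10-bin estimator so the
two power-law readouts are comparable.

## Topological overlap

The unsigned TOM is
T_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij), ℓ_ij = Σ_u a_iu a_uj,
with unit diagonal; a pair of mutually isolated genes (zero denominator)
gets T = 0. The ℓ term is a matrix product, optionally computed in row
blocks with bit-identical results to bound memory on large gene sets.
Symmetry is enforced by averaging T with its transpose (round-off only;
tolerance well below 1e−10). Thresholded networks use a strict
inequality (T > cutoff), report only incident nodes, and order each edge
with the lexicographically smaller gene first.

## Module detection

Genes are clustered by average-linkage agglomerative hierarchical
clustering on the TOM dissimilarity D = 1 − T. The dendrogram is cut by a
branch-aware procedure in the dynamic-hybrid style, reimplemented here
(exact equivalence with reference implementations is not promised; the
validation surface is recovery of planted structure):

1. **Static stage.** Merges above 0.99 × root height are always split.
   This detaches the major branches and the outlier genes that chain onto
   branches just below the root, where merge heights carry no contrast.
2. **Core-scatter stage.** Below the static cut, a merge is split when
   its height exceeds mean + c·sd of the merge heights inside its own
   subtree — a merge far above its branch's core scatter joins things
   that do not belong together. The fence c maps from deepSplit as
   {0: 5.0, 1: 4.0, 2: 3.0, 3: 2.5, 4: 2.0}; higher deepSplit means a
   tighter fence and more aggressive splitting into smaller clusters.
   Subtrees with fewer than three internal merges are never split by this
   rule. Running subtree moments make the whole decomposition O(n).
3. **Size gate.** Branches smaller than `min_module_size` (default 30)
   are stripped to the unassigned label 0 ("grey").
4. **PAM-like stage.** Each unassigned gene is attached to the cluster
   with the smallest average dissimilarity, but only if that average lies
   within the cluster's radius (the maximum member-to-cluster average
   distance), so noise genes far from every module stay grey.

Module labels are contiguous 1..M in decreasing size order (ties by first
gene position), with the color-name convention (turquoise, blue, brown,
…) applied by size rank in the TSV export. The procedure is fully
deterministic.

**Eigengenes.** Each module's submatrix is standardized per gene (mean 0,
sd 1; a constant gene makes the module's eigengene undefined and is a
hard error naming the module) and decomposed by SVD. The eigengene is the
first right-singular direction across samples, unit norm, sign-fixed so
its correlation with the module's mean standardized profile is
non-negative; explained variance is σ₁²/Σσ². The module relationship tree
is average-linkage clustering of 1 − Pearson between eigengenes.

## Network topology

Statistics are computed on the simple undirected graph of a thresholded
network: degrees, average neighbors 2·E/N, breadth-first (unweighted)
shortest-path length histogram counting each connected unordered pair
once, and the diameter of the largest connected component (a disconnected
graph has no finite global diameter; the largest component is the
convention used for the single reported value). Hub genes are those with
degree at or above the cutoff (non-strict), sorted by degree then
identifier.

## Greedy Steiner sub-network

Seeds are terminals with zero node cost; edge cost is 1 − weight. Every
seed present in the network starts as a singleton tree, and the pair of
trees connected by the cheapest shortest path is merged repeatedly until
one tree remains or the survivors are mutually unreachable (then the tree
holding the most seeds is kept and the rest are counted as dropped,
alongside seeds absent from the network). The tree is pruned so every
leaf is a seed; interior non-seeds are the linker genes. Path-cost ties
break by the lexicographically smallest node-id sequence, making the
result deterministic. The greedy merge heuristic carries the classic
2-approximation guarantee relative to the Steiner optimum, which the test
suite verifies empirically against exhaustive enumeration on small
graphs.

Because a co-expression sub-network is reported as an interaction map
rather than a spanning skeleton, all direct network edges among the
included nodes are re-added to the reported edge set after pruning;
`total_cost` refers to the spanning tree only.

## Enrichment

Over-representation of a query list in each gene set is the upper-tail
hypergeometric probability P(X ≥ k) given an explicit background size
(e.g. all 24,616 annotated genes of a genome); q-values are
Benjamini–Hochberg step-up within the collection (separate collections,
e.g. KEGG vs GO, are separate calls). The background size is a required
parameter because annotation-aware backgrounds differ between tools; when
an explicit universe gene list is supplied, query genes outside it are
dropped with a warning, otherwise the query is used as given.

## Synthetic data: what it emulates and what it does not

The generator draws, per module, a latent profile e_m with independent
standard-normal entries over samples; a member gene observes
u_j · e_m + ε with membership strength u_j uniform in the module's
strength range and ε ~ N(0, noise_sd²). Background genes are pure noise;
non-informative genes are positive in fewer than half the samples and
zero elsewhere (so the presence filter at half the samples removes
exactly them). Values are made FPKM-like by a per-gene shift to a zero
minimum — location-only, so the correlation structure is untouched. One
integer seed drives deterministically spawned per-block substreams;
identical specs give bit-identical matrices.

The latent-factor form is chosen deliberately: the eigengene (first
singular direction) is precisely the natural estimator of e_m, so
eigengene-recovery tests are principled rather than circular. The default
conditions use six modules with skewed sizes (120 down to 30 genes) and
broad strengths [0.3, 1.0] — strong-membership genes act as hub genes,
and mapping a broad strength distribution through u^β produces a
decaying, scale-free-like connectivity distribution. The documented
recovery regime (strengths [0.7, 1.0], noise sd ≤ 0.2) is the regime in
which module recovery is tested: adjusted Rand index ≥ 0.9 against the
planted partition and |correlation| ≥ 0.9 between detected eigengenes and
latent factors, over five seeds.

What the generator does **not** emulate: RNA-seq count noise (negative
binomial sampling), library-size artifacts, batch effects, overlapping
module membership, or correlated latent factors. Passing the recovery
tests therefore demonstrates correctness of the estimators under the
model they assume, not robustness to every pathology of real expression
data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline on
matrices of roughly 300–460 genes × 92 samples — large enough for the
planted structure to behave like a real co-expression matrix, small
enough to iterate on quickly; all stages scale to the 5,000-gene setting
the defaults (top 5,000 MAD genes, TOM row blocks) are designed around.
Other fixed choices: 10 bins for both power-law fits; strict inequality
at TOM cutoffs; symmetry enforcement by transpose-averaging; hypergeometric
tails via scipy, BH via statsmodels, clustering via scipy, graph
statistics via networkx.

## Known limitations

* The dynamic tree cut is a reimplementation in the hybrid style, not a
  port; branch decompositions can differ from other implementations on
  ambiguous dendrograms, and module counts on real data are sensitive to
  deepSplit and the minimum size.
* The greedy Steiner heuristic guarantees only a 2-approximation; exact
  solutions exist in the tests solely for graphs small enough to
  enumerate.
* bicor's Pearson fallback applies to whole rows of zero-MAD genes rather
  than per-pair hybrid weighting.
* Signed or "signed hybrid" adjacency variants and module merging by
  eigengene similarity are not implemented; the adjacency is unsigned by
  design.
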