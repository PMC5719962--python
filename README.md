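# coexnet

Weighted gene co-expression interactome construction for multi-tissue
expression profiles — the WGCNA-style workflow used to build a
co-expression reference network from normalized FPKM values across many
tissues (the motivating use case is a 92-tissue *Bos taurus* expression
atlas), exposed as a tested, reusable Python library and command-line
pipeline.

It is aimed at systems-biology researchers who want to go from a
genes × samples expression matrix to an interactome they can mine:
functional modules with eigengene summaries, hub genes, minimal
sub-networks spanning a gene list of interest, and gene-set enrichment
of the results.

## The method

Starting from a genes × samples matrix of non-negative expression values
(normalized FPKM), the pipeline runs:

1. **Filtering.** Genes expressed (value > 0) in no more than half of the
   samples are removed as non-informative; the remaining genes are ranked
   by median absolute deviation (MAD) and the top *N* (default 5,000) most
   variable genes are kept.
2. **Robust similarity.** The biweight midcorrelation *S*: with
   *u* = (*x* − med *x*) / (9·MAD *x*), samples are weighted by
   *w* = (1 − *u*²)²·1[|*u*| < 1] before correlating, so single outlying
   tissues cannot dominate a gene pair. Zero-MAD genes fall back to
   Pearson.
3. **Soft threshold.** Adjacency *a*ᵢⱼ = |*S*ᵢⱼ|^β. The power β is chosen
   by the scale-free topology criterion: the smallest β whose
   connectivity distribution satisfies the log *p*(*k*) ~ log *k*
   regression with signed *R*² ≥ 0.8.
4. **Topological overlap.** *T*ᵢⱼ = (ℓᵢⱼ + *a*ᵢⱼ) / (min(*k*ᵢ, *k*ⱼ) + 1 −
   *a*ᵢⱼ) with ℓᵢⱼ = Σᵤ *a*ᵢᵤ*a*ᵤⱼ, rewarding gene pairs that share
   neighbors. Thresholding *T* (defaults 0.01 / 0.1 / 0.3) yields
   undirected weighted interactomes as edge lists.
5. **Modules.** Average-linkage hierarchical clustering on 1 − *T*, cut by
   a dynamic (branch-aware) tree cut controlled by a deepSplit parameter
   (0–4) and a minimum module size (default 30); each module is summarized
   by its eigengene, the first singular direction across samples of the
   standardized module submatrix, and modules are related by a tree on
   eigengene correlations.
6. **Topology and hubs.** Degree distribution with a binned log–log
   power-law fit, unweighted shortest-path histogram, diameter, average
   neighbors 2·E/N, and hub calling at a degree cutoff (default ≥ 100).
7. **Sub-networks.** For a seed gene list, a greedy Steiner-tree heuristic
   (edge cost 1 − *T*; singleton trees iteratively merged along
   cheapest paths) extracts a minimal connected sub-network; non-seed
   genes required for connectivity are reported as linkers.
8. **Enrichment.** Upper-tail hypergeometric over-representation of a gene
   list against GMT gene sets with Benjamini–Hochberg correction, against
   an explicit background size.

A synthetic-data generator plants known structure — latent eigengene
factors with per-gene membership strengths, background noise genes,
non-informative genes, hub-like strong members — so every stage is
testable against ground truth without any download.

## Worked example

```python
import numpy as np
import coexnet as cx
from coexnet.simulate import SyntheticSpec

spec = SyntheticSpec(
    n_samples=92,
    modules=[(m, 50, (0.7, 1.0)) for m in range(1, 7)],
    n_background_genes=20,
    n_noninformative_genes=10,
    noise_sd=0.2,
    random_seed=0,
)
matrix, truth = cx.generate(spec)
matrix, report = cx.presence_filter(matrix, matrix.n_samples // 2)
print(f"genes after presence filter: {matrix.n_genes} (of {report.n_input_genes})")

S = cx.bicor_matrix(matrix)
T = cx.tom(cx.adjacency(S, beta=4))
net = cx.threshold_network(T, 0.1)
print(f"TOM > 0.1 interactome: {net.n_nodes} genes, {net.n_edges} co-expression pairs")

assign = cx.dynamic_cut(cx.cluster_genes(T), T.dissimilarity(), T.gene_ids,
                        deep_split=4, min_module_size=30)
print(f"modules detected: {assign.n_modules}, unassigned (grey) genes: {assign.n_unassigned()}")

E = cx.eigengenes(matrix, assign)
r = np.corrcoef(E.profiles[1], truth.eigengene_of[1])[0, 1]
print(f"module 1: {len(assign.members(1))} genes, "
      f"eigengene vs planted factor |r| = {abs(r):.3f}")
```

prints

```
genes after presence filter: 320 (of 330)
TOM > 0.1 interactome: 300 genes, 7350 co-expression pairs
modules detected: 6, unassigned (grey) genes: 25
module 1: 50 genes, eigengene vs planted factor |r| = 0.999
```

The presence filter removed exactly the 10 planted non-informative genes;
at this threshold each planted 50-gene module forms a tight co-expression
cluster, the tree cut recovers all six (25 background genes stay grey),
and the module eigengene is essentially the planted latent factor.

The same pipeline is scriptable from a shell:

```sh
coexnet simulate --seed 0 --out-dir run/
coexnet all --expr run/expression.tsv --out-dir run/ --top-n 5000
coexnet subnet --edges run/network_tom_0.1.tsv --seeds my_seeds.txt --out-dir run/
coexnet enrich --query module1_genes.txt --gmt annotations.gmt \
    --background-size 24616 --out-dir run/
```

All outputs are plain TSV (edge lists are Cytoscape-loadable); parameters
and SHA-256 hashes of every output are logged to stderr, and reruns on
unchanged inputs are byte-identical.

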