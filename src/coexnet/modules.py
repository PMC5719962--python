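"""Module detection: hierarchical clustering on TOM dissimilarity, a
dynamic (branch-aware) tree cut, module eigengenes and the module
relationship tree.

The tree cut is a hybrid-style reimplementation of dynamic branch
decomposition: walking the average-linkage dendrogram from the root, a
merge node is split when at least one of its children hangs sufficiently
far below the merge height (the "gap" criterion). The required gap is a
fraction of the dendrogram height controlled by ``deep_split`` (0–4;
higher = smaller required gap = more aggressive splitting into smaller
clusters). Branches smaller than ``min_module_size`` are stripped to the
unassigned label 0, and a PAM-like second stage assigns each unassigned
gene to the nearest qualifying cluster when it lies within that cluster's
radius. Exact equivalence with R's ``cutreeDynamic`` is not promised; the
procedure is validated by recovery of planted structure.

Eigengenes summarize a module: after per-gene standardization the module
submatrix is decomposed by SVD and the eigengene is the first singular
direction across samples (unit norm, sign aligned with the module's mean
expression profile). Its explained variance fraction is sigma_1^2 / sum
sigma^2.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix
from .tom import TOMMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleAssignment",
    "EigengeneMatrix",
    "cluster_genes",
    "dynamic_cut",
    "eigengenes",
    "module_tree",
    "MODULE_COLORS",
]

# core-scatter fence per deep_split level: a merge is split when its height
# exceeds mean + c * sd of the merge heights in its subtree (its "core").
# Higher deep_split -> tighter fence -> more aggressive splitting.
_SCATTER_FENCE = {0: 5.0, 1: 4.0, 2: 3.0, 3: 2.5, 4: 2.0}

# size-rank color convention for reporting
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta",
]


@dataclass
class ModuleAssignment:
    """Gene → module label; 0 is the unassigned ("grey") sentinel.

    Labels are contiguous 1..M ordered by decreasing module size.
    """

    gene_ids: list[str]
    labels: np.ndarray  # int array aligned with gene_ids
    deep_split: int
    min_module_size: int

    @property
    def n_modules(self) -> int:
        return int(self.labels.max(initial=0))

    def module_sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for lab in self.labels:
            if lab > 0:
                out[int(lab)] = out.get(int(lab), 0) + 1
        return out

    def n_unassigned(self) -> int:
        return int(np.sum(self.labels == 0))

    def members(self, label: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]

    def write_tsv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["gene_id", "module_label", "module_color"])
            for g, lab in zip(self.gene_ids, self.labels):
                if lab == 0:
                    color = "grey"
                else:
                    color = (
                        MODULE_COLORS[lab - 1]
                        if lab - 1 < len(MODULE_COLORS)
                        else f"module{lab}"
                    )
                w.writerow([g, int(lab), color])


@dataclass
class EigengeneMatrix:
    """Module label → unit-norm eigengene profile across samples."""

    sample_ids: list[str]
    profiles: dict[int, np.ndarray]
    explained_variance: dict[int, float]

    def write_tsv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["module", *self.sample_ids, "explained_variance"])
            for lab in sorted(self.profiles):
                w.writerow(
                    [lab, *(repr(float(v)) for v in self.profiles[lab]),
                     repr(self.explained_variance[lab])]
                )


def cluster_genes(T: TOMMatrix):
    """Average-linkage agglomerative clustering on D = 1 - TOM.

    Returns a scipy linkage matrix over the genes in T's order.
    """
    n = len(T.gene_ids)
    if n < 2:
        raise ValueError("need >= 2 genes to cluster")
    D = T.dissimilarity().copy()
    np.fill_diagonal(D, 0.0)
    return average(squareform(D, checks=False))


def dynamic_cut(
    linkage: np.ndarray,
    D: np.ndarray,
    gene_ids: list[str],
    deep_split: int = 4,
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> ModuleAssignment:
    """Branch-aware cut of a dendrogram into modules.

    Merges above ``cut_height`` × (root height) are always split — the
    static stage that detaches the major branches and outlier genes
    chained just below the root. Below it, a merge is split when its
    height lies more than ``c`` standard deviations above the mean merge
    height of its own subtree (the branch core), with ``c`` controlled by
    ``deep_split``: a merge far above its core scatter joins things that
    do not belong together. ``D`` is the gene × gene dissimilarity used
    for the PAM-like stage. Deterministic given its inputs.
    """
    if deep_split not in _SCATTER_FENCE:
        raise ValueError("deep_split must be in {0,1,2,3,4}")
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    n = len(gene_ids)
    if linkage.shape[0] != n - 1:
        raise ValueError("linkage does not match gene count")

    if not 0 < cut_height <= 1:
        raise ValueError("cut_height must be in (0, 1]")
    heights = linkage[:, 2]
    root_h = float(heights.max())
    fence_c = _SCATTER_FENCE[deep_split]
    static_cut = cut_height * root_h

    # subtree bookkeeping: node ids 0..n-1 leaves, n..2n-2 internal;
    # running moments of the merge heights below each node give the
    # core-scatter fence in O(n)
    n_leaves = np.ones(2 * n - 1, dtype=int)
    node_h = np.zeros(2 * n - 1)
    children = np.zeros((n - 1, 2), dtype=int)
    n_merges = np.zeros(2 * n - 1, dtype=int)
    h_sum = np.zeros(2 * n - 1)
    h_sumsq = np.zeros(2 * n - 1)
    for i in range(n - 1):
        a, b = int(linkage[i, 0]), int(linkage[i, 1])
        children[i] = (a, b)
        n_leaves[n + i] = n_leaves[a] + n_leaves[b]
        node_h[n + i] = heights[i]
        n_merges[n + i] = n_merges[a] + n_merges[b] + 1
        h_sum[n + i] = h_sum[a] + h_sum[b] + heights[i]
        h_sumsq[n + i] = h_sumsq[a] + h_sumsq[b] + heights[i] ** 2

    def _splits(node: int) -> bool:
        """Does this merge join things that do not belong together?"""
        if node_h[node] > static_cut:
            return True
        a, b = children[node - n]
        m = n_merges[a] + n_merges[b]  # core merges strictly below node
        if m < 3:
            return False
        mean = (h_sum[a] + h_sum[b]) / m
        var = max((h_sumsq[a] + h_sumsq[b]) / m - mean**2, 0.0)
        return node_h[node] > mean + fence_c * np.sqrt(var)

    def leaves_of(node: int) -> list[int]:
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                stack.extend(children[v - n])
        return out

    clusters: list[list[int]] = []
    strays: list[int] = []

    def consume(node: int) -> None:
        if n_leaves[node] >= min_module_size:
            work.append(node)
        else:
            strays.extend(leaves_of(node))

    work: list[int] = []
    consume(2 * n - 2)
    while work:
        node = work.pop()
        if node < n:  # single leaf cannot be a module (min size >= 2)
            strays.append(node)
            continue
        a, b = children[node - n]
        if _splits(node):
            consume(a)
            consume(b)
        else:
            clusters.append(leaves_of(node))

    if not clusters:
        warnings.warn("no cluster reached min_module_size; all genes unassigned")
        return ModuleAssignment(list(gene_ids), np.zeros(n, dtype=int),
                                deep_split, min_module_size)

    # PAM-like stage: attach strays to the nearest cluster, but only when
    # they fall inside its radius (max member-to-cluster average distance).
    labels = np.zeros(n, dtype=int)
    for ci, members in enumerate(clusters, start=1):
        labels[members] = ci
    radii = []
    centers = []
    for members in clusters:
        sub = D[np.ix_(members, members)]
        avg_within = (sub.sum(axis=1)) / max(len(members) - 1, 1)
        radii.append(float(avg_within.max()))
        centers.append(np.array(members))
    n_attached = 0
    for g in sorted(strays):
        best = None
        for ci, members in enumerate(centers):
            d = float(D[g, members].mean())
            if best is None or d < best[0]:
                best = (d, ci)
        if best is not None and best[0] <= radii[best[1]]:
            labels[g] = best[1] + 1
            n_attached += 1
    logger.info(
        "dynamic cut (deep_split=%d, min size=%d): %d clusters, %d strays "
        "(%d attached in PAM stage)",
        deep_split, min_module_size, len(clusters), len(strays), n_attached,
    )

    # relabel 1..M by decreasing size; ties by smallest first gene index
    sizes: dict[int, int] = {}
    first: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab > 0:
            sizes[lab] = sizes.get(lab, 0) + 1
            first.setdefault(lab, i)
    order = sorted(sizes, key=lambda l: (-sizes[l], first[l]))
    remap = {old: new for new, old in enumerate(order, start=1)}
    final = np.array([remap.get(int(l), 0) for l in labels], dtype=int)
    return ModuleAssignment(list(gene_ids), final, deep_split, min_module_size)


def eigengenes(m: ExpressionMatrix, assign: ModuleAssignment) -> EigengeneMatrix:
    """First singular direction across samples of each module's
    standardized submatrix."""
    gene_index = {g: i for i, g in enumerate(m.gene_ids)}
    profiles: dict[int, np.ndarray] = {}
    explained: dict[int, float] = {}
    for lab in sorted(set(int(l) for l in assign.labels) - {0}):
        members = assign.members(lab)
        missing_members = [g for g in members if g not in gene_index]
        if missing_members:
            raise ValueError(
                f"module {lab}: genes absent from expression matrix: "
                f"{missing_members[:5]}"
            )
        X = m.values[[gene_index[g] for g in members]].astype(float)
        X = np.where(np.isnan(X), np.nanmean(X, axis=1, keepdims=True), X)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError(f"module {lab} contains constant genes; eigengene undefined")
        Z = (X - mu) / sd
        _, s, Vt = np.linalg.svd(Z, full_matrices=False)
        e = Vt[0]
        e = e / np.linalg.norm(e)
        mean_profile = Z.mean(axis=0)
        if float(np.dot(e, mean_profile)) < 0:
            e = -e
        profiles[lab] = e
        explained[lab] = float(s[0] ** 2 / np.sum(s**2))
    return EigengeneMatrix(list(m.sample_ids), profiles, explained)


def module_tree(E: EigengeneMatrix):
    """Average-linkage tree over modules on 1 - Pearson(eigengene pairs).

    Returns (module_labels_in_row_order, scipy linkage matrix).
    """
    labs = sorted(E.profiles)
    if len(labs) < 2:
        raise ValueError("need >= 2 modules for a relationship tree")
    M = np.array([E.profiles[l] for l in labs])
    C = np.corrcoef(M)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    return labs, average(squareform(D, checks=False))
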