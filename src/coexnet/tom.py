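"""Topological overlap and thresholded co-expression networks.

The topological overlap matrix (TOM) rewards gene pairs that are not only
directly connected but also share neighbors: with l_ij = sum_u a_iu a_uj
and k_i = sum_u a_iu, the unsigned TOM is

    T_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),   T_ii = 1.

Thresholding T at a cutoff yields an undirected weighted edge list — the
co-expression interactome at that stringency.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np

from .correlation import AdjacencyMatrix

logger = logging.getLogger(__name__)

__all__ = ["TOMMatrix", "CoexpressionNetwork", "tom", "threshold_network",
           "write_edge_list", "read_edge_list"]


@dataclass
class TOMMatrix:
    gene_ids: list[str]
    T: np.ndarray  # symmetric, [0, 1], unit diagonal

    def dissimilarity(self) -> np.ndarray:
        """1 - T, the clustering input."""
        return 1.0 - self.T


@dataclass
class CoexpressionNetwork:
    """Thresholded network: nodes are exactly the genes incident to >= 1
    edge; edges are (gene_a, gene_b, weight) with gene_a < gene_b."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    threshold: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g


def tom(A: AdjacencyMatrix, block_size: int | None = None) -> TOMMatrix:
    """Unsigned TOM of an adjacency matrix.

    The shared-neighbor term is a matrix product, computed in row blocks of
    ``block_size`` when given (identical result, bounded memory). A pair
    with zero denominator (two mutually isolated genes) gets T = 0.
    """
    a = A.A
    n = a.shape[0]
    k = a.sum(axis=1)
    T = np.empty_like(a)
    if block_size is None or block_size >= n:
        L = a @ a
        _tom_fill(T, L, a, k, 0, n)
    else:
        for start in range(0, n, block_size):
            stop = min(start + block_size, n)
            L = a[start:stop] @ a
            _tom_fill(T, L, a, k, start, stop)
    T = (T + T.T) / 2.0  # enforce symmetry against float round-off
    np.clip(T, 0.0, 1.0, out=T)
    np.fill_diagonal(T, 1.0)
    return TOMMatrix(list(A.gene_ids), T)


def _tom_fill(T, L, a, k, start, stop) -> None:
    kmin = np.minimum(k[start:stop, None], k[None, :])
    denom = kmin + 1.0 - a[start:stop]
    num = L + a[start:stop]
    with np.errstate(divide="ignore", invalid="ignore"):
        block = np.where(denom > 0, num / denom, 0.0)
    T[start:stop] = block


def threshold_network(T: TOMMatrix, cutoff: float) -> CoexpressionNetwork:
    """Edges for every unordered pair with T strictly above ``cutoff``.

    The inequality is strict, so a cutoff of 1 yields an empty network
    (the unit diagonal is never an edge).
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    n = len(T.gene_ids)
    iu, ju = np.triu_indices(n, k=1)
    w = T.T[iu, ju]
    keep = w > cutoff
    edges = []
    for i, j, wij in zip(iu[keep], ju[keep], w[keep]):
        a, b = T.gene_ids[i], T.gene_ids[j]
        if b < a:
            a, b = b, a
        edges.append((a, b, float(wij)))
    edges.sort()
    nodes = sorted({g for a, b, _ in edges for g in (a, b)})
    logger.info("TOM > %g: %d nodes, %d edges", cutoff, len(nodes), len(edges))
    return CoexpressionNetwork(nodes, edges, float(cutoff))


def write_edge_list(net: CoexpressionNetwork, path: str) -> None:
    """Cytoscape-loadable TSV: gene_a, gene_b, weight."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_a", "gene_b", "weight"])
        for a, b, wt in net.edges:
            w.writerow([a, b, repr(wt)])


def read_edge_list(path: str, threshold: float = 0.0) -> CoexpressionNetwork:
    edges = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        for row in reader:
            if not row:
                continue
            a, b, wt = row[0], row[1], float(row[2])
            if b < a:
                a, b = b, a
            edges.append((a, b, wt))
    edges.sort()
    nodes = sorted({g for a, b, _ in edges for g in (a, b)})
    return CoexpressionNetwork(nodes, edges, threshold)
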