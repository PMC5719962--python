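"""Network topology statistics and hub calling.

Works on the thresholded co-expression network as a simple undirected
graph: degree distribution with a binned log-log power-law fit, unweighted
shortest-path length histogram (paths are counted in steps), diameter of
the largest connected component, and hub genes at a degree cutoff.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .correlation import fit_powerlaw
from .tom import CoexpressionNetwork

logger = logging.getLogger(__name__)

__all__ = ["TopologyReport", "analyze", "hubs"]


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    degree: dict[str, int]
    avg_neighbors: float
    diameter: int
    path_length_histogram: dict[int, int]
    powerlaw_exponent: float
    powerlaw_r2: float
    n_components: int
    largest_component_size: int
    degree_fit_bins: int = field(default=10)

    def write_tsv(self, path: str, degree_path: str | None = None) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["statistic", "value"])
            w.writerow(["n_nodes", self.n_nodes])
            w.writerow(["n_edges", self.n_edges])
            w.writerow(["avg_neighbors", repr(self.avg_neighbors)])
            w.writerow(["diameter", self.diameter])
            w.writerow(["powerlaw_exponent", repr(self.powerlaw_exponent)])
            w.writerow(["powerlaw_r2", repr(self.powerlaw_r2)])
            w.writerow(["n_components", self.n_components])
            w.writerow(["largest_component_size", self.largest_component_size])
            for length in sorted(self.path_length_histogram):
                w.writerow([f"path_length_{length}", self.path_length_histogram[length]])
        if degree_path is not None:
            with open(degree_path, "w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(["gene_id", "degree"])
                for g, d in sorted(self.degree.items(), key=lambda kv: (-kv[1], kv[0])):
                    w.writerow([g, d])


def analyze(net: CoexpressionNetwork, n_bins: int = 10) -> TopologyReport:
    """Full topology report for a non-empty network.

    Shortest paths are breadth-first (unweighted); the histogram counts
    each connected unordered pair once. The degree-distribution exponent
    is the negated slope of the same binned log-log regression used for
    the scale-free criterion, reported positive for decaying
    distributions.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    g = net.to_networkx()
    degree = {v: int(d) for v, d in g.degree()}
    n_nodes, n_edges = g.number_of_nodes(), g.number_of_edges()
    avg_neighbors = 2.0 * n_edges / n_nodes

    components = sorted(nx.connected_components(g), key=len, reverse=True)
    largest = g.subgraph(components[0])

    largest_nodes = set(largest.nodes())
    hist: dict[int, int] = {}
    diameter = 0  # of the largest component (single finite convention)
    for src, dists in nx.all_pairs_shortest_path_length(g):
        in_largest = src in largest_nodes
        for d in dists.values():
            if d > 0:
                hist[d] = hist.get(d, 0) + 1
                if in_largest and d > diameter:
                    diameter = d
    hist = {d: c // 2 for d, c in hist.items()}  # each unordered pair counted twice

    degs = np.array(sorted(degree.values()))
    r2, slope = fit_powerlaw(degs.astype(float), n_bins=n_bins)
    exponent = -slope

    report = TopologyReport(
        n_nodes=n_nodes,
        n_edges=n_edges,
        degree=degree,
        avg_neighbors=avg_neighbors,
        diameter=diameter,
        path_length_histogram=hist,
        powerlaw_exponent=float(exponent),
        powerlaw_r2=float(r2),
        n_components=len(components),
        largest_component_size=largest.number_of_nodes(),
        degree_fit_bins=n_bins,
    )
    logger.info(
        "topology: %d nodes, %d edges, diameter %d, avg neighbors %.3f, exponent %.3f",
        n_nodes, n_edges, diameter, avg_neighbors, exponent,
    )
    return report


def hubs(net: CoexpressionNetwork, min_degree: int) -> list[tuple[str, int]]:
    """Genes with degree >= ``min_degree`` (non-strict), sorted by degree
    descending then gene id."""
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    g = net.to_networkx()
    out = [(v, int(d)) for v, d in g.degree() if d >= min_degree]
    out.sort(key=lambda vd: (-vd[1], vd[0]))
    return out
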