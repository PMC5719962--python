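"""Greedy Steiner-tree extraction of a seed-gene sub-network.

Given a weighted co-expression network and a set of seed genes
(terminals), the goal is a minimal-cost connected subgraph spanning the
seeds; non-seed genes pulled in to achieve connectivity are "linkers".
Edge cost is 1 - weight, and seeds themselves carry zero cost.

The heuristic is greedy tree merging: every seed present in the network
starts as its own singleton tree; repeatedly the pair of trees connected
by the cheapest path (shortest path under edge cost) is merged by adding
that path, until one tree remains or the survivors are mutually
unreachable. The result is pruned so every leaf is a seed, and all direct
network edges among the included nodes are then re-added to the reported
edge set (the tree determines membership; the report shows the induced
interactions). The classic guarantee for this family of heuristics is a
cost within 2x of the Steiner optimum.

Ties in path cost are broken by the lexicographically smallest node-id
sequence, so results are deterministic.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import networkx as nx

from .tom import CoexpressionNetwork

logger = logging.getLogger(__name__)

__all__ = ["SubnetworkResult", "extract", "read_seed_list", "write_subnetwork"]


@dataclass
class SubnetworkResult:
    nodes: list[tuple[str, str]]  # (gene, role in {"seed", "linker"})
    edges: list[tuple[str, str, float]]
    n_seed_in: int
    n_seed_dropped: int
    total_cost: float  # sum of (1 - weight) over the spanning tree's edges
    tree_edges: list[tuple[str, str, float]] | None = None

    @property
    def linkers(self) -> list[str]:
        return [g for g, role in self.nodes if role == "linker"]

    @property
    def seeds_included(self) -> list[str]:
        return [g for g, role in self.nodes if role == "seed"]


def read_seed_list(path: str) -> list[str]:
    """One gene identifier per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_subnetwork(res: SubnetworkResult, node_path: str, edge_path: str) -> None:
    import csv

    with open(node_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "role"])
        for g, role in res.nodes:
            w.writerow([g, role])
    with open(edge_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_a", "gene_b", "weight"])
        for a, b, wt in res.edges:
            w.writerow([a, b, repr(wt)])


def _tree_dijkstra(g: nx.Graph, sources: frozenset[str]) -> dict[str, tuple[float, tuple[str, ...]]]:
    """Cheapest (cost, path) from a set of zero-cost sources to every node.

    Path tuples participate in the heap ordering, which realizes the
    lexicographic tie-break exactly.
    """
    best: dict[str, tuple[float, tuple[str, ...]]] = {}
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (s,)) for s in sorted(sources)]
    heapq.heapify(heap)
    while heap:
        cost, path = heapq.heappop(heap)
        node = path[-1]
        if node in best:
            continue
        best[node] = (cost, path)
        for nbr, attrs in g[node].items():
            if nbr not in best:
                heapq.heappush(heap, (cost + (1.0 - attrs["weight"]), path + (nbr,)))
    return best


def extract(net: CoexpressionNetwork, seeds: list[str]) -> SubnetworkResult:
    """Greedy Steiner sub-network over ``seeds`` in ``net``.

    Seeds absent from the network, and seeds whose trees can never be
    connected to the kept component, are counted in ``n_seed_dropped``.
    When the surviving trees are mutually unreachable, the tree holding
    the most seeds is kept (tie: lexicographically smallest seed).
    """
    if not seeds:
        raise ValueError("seed list is empty")
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    seed_set = sorted(set(seeds))
    g = net.to_networkx()
    present = [s for s in seed_set if s in g]
    absent = [s for s in seed_set if s not in g]
    if not present:
        raise ValueError(f"no seed present in the network: {seed_set}")

    # each present seed starts as a singleton tree
    trees: dict[int, dict] = {
        i: {"nodes": {s}, "edges": set(), "seeds": {s}} for i, s in enumerate(present)
    }
    node_tree = {s: i for i, s in enumerate(present)}
    dist_cache: dict[int, dict[str, tuple[float, tuple[str, ...]]]] = {}

    while len(trees) > 1:
        best_merge = None  # (cost, path, tid_a, tid_b)
        for tid in sorted(trees):
            if tid not in dist_cache:
                dist_cache[tid] = _tree_dijkstra(g, frozenset(trees[tid]["nodes"]))
            dists = dist_cache[tid]
            for other in sorted(trees):
                if other == tid:
                    continue
                for node in sorted(trees[other]["nodes"]):
                    hit = dists.get(node)
                    if hit is None:
                        continue
                    cand = (hit[0], hit[1], tid, other)
                    if best_merge is None or cand[:2] < best_merge[:2]:
                        best_merge = cand
        if best_merge is None:
            break  # remaining trees mutually unreachable
        cost, path, ta, tb = best_merge
        a, b = trees[ta], trees[tb]
        merged_nodes = a["nodes"] | b["nodes"] | set(path)
        merged_edges = a["edges"] | b["edges"]
        for u, v in zip(path[:-1], path[1:]):
            x, y = (u, v) if u < v else (v, u)
            merged_edges.add((x, y))
        keep = min(ta, tb)
        drop = max(ta, tb)
        trees[keep] = {
            "nodes": merged_nodes,
            "edges": merged_edges,
            "seeds": a["seeds"] | b["seeds"],
        }
        del trees[drop]
        dist_cache.pop(ta, None)
        dist_cache.pop(tb, None)
        # path interior may touch a third tree's territory only via shared
        # non-tree nodes; tree node sets stay disjoint because paths start
        # and end at the two merged trees
        for nd in merged_nodes:
            node_tree[nd] = keep

    # keep the tree with the most seeds (tie: smallest seed id)
    kept_id = min(trees, key=lambda t: (-len(trees[t]["seeds"]), min(trees[t]["seeds"])))
    kept = trees[kept_id]
    dropped_reachable = set(present) - kept["seeds"]

    # prune: every leaf of the tree must be a seed
    tg = nx.Graph()
    tg.add_nodes_from(kept["nodes"])
    tg.add_edges_from(kept["edges"])
    seed_in = set(kept["seeds"])
    changed = True
    while changed:
        changed = False
        for v in sorted(tg.nodes()):
            if v not in seed_in and tg.degree(v) <= 1:
                tg.remove_node(v)
                changed = True

    tree_edges = []
    total_cost = 0.0
    for u, v in sorted(tuple(sorted(e)) for e in tg.edges()):
        w = float(g[u][v]["weight"])
        tree_edges.append((u, v, w))
        total_cost += 1.0 - w

    # report the induced direct interactions among included nodes
    members = sorted(tg.nodes())
    member_set = set(members)
    edges = []
    for u in members:
        for v, attrs in g[u].items():
            if v in member_set and u < v:
                edges.append((u, v, float(attrs["weight"])))
    edges.sort()

    nodes = [(gid, "seed" if gid in seed_in else "linker") for gid in members]
    n_dropped = len(absent) + len(dropped_reachable)
    logger.info(
        "sub-network: %d nodes (%d seeds, %d linkers), %d induced edges, "
        "%d seeds dropped, tree cost %.4f",
        len(nodes), len(seed_in & member_set), len(members) - len(seed_in & member_set),
        len(edges), n_dropped, total_cost,
    )
    return SubnetworkResult(
        nodes=nodes,
        edges=edges,
        n_seed_in=len(seed_in & member_set),
        n_seed_dropped=n_dropped,
        total_cost=total_cost,
        tree_edges=tree_edges,
    )
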