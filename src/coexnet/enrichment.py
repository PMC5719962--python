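"""Gene-set over-representation analysis.

For a query gene list and a collection of annotation sets (GMT format),
each set is scored by the upper-tail hypergeometric probability of
observing at least the actual overlap, given the background universe
size; raw p-values are corrected across the collection by
Benjamini–Hochberg step-up. The background size is an explicit, required
parameter (the study used all 24,616 Ensembl genes).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "EnrichmentTable", "read_gmt", "hypergeom_enrich",
           "bh_adjust"]


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), capped at 1."""
    if not pvalues:
        return []
    q = multipletests(pvalues, method="fdr_bh")[1]
    return [float(min(v, 1.0)) for v in q]


@dataclass
class GeneSetCollection:
    """set_id → (description, members), plus the background universe size.

    ``universe`` optionally lists the background genes explicitly; when
    present, query genes outside it are dropped (with a warning) before
    testing.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    background_size: int
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for sid, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {sid!r} is empty")
            if len(members) > self.background_size:
                raise ValueError(
                    f"gene set {sid!r} larger ({len(members)}) than background "
                    f"({self.background_size})"
                )
        if self.universe is not None and len(self.universe) != self.background_size:
            raise ValueError("explicit universe size differs from background_size")


@dataclass
class EnrichmentTable:
    rows: list[dict] = field(default_factory=list)  # set_id, description, n_overlap, p_value, q_value

    def write_tsv(self, path: str) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["set_id", "description", "n_overlap", "p_value", "q_value"])
            for r in self.rows:
                w.writerow(
                    [r["set_id"], r["description"], r["n_overlap"],
                     repr(r["p_value"]), repr(r["q_value"])]
                )


def read_gmt(path: str, background_size: int,
             universe: set[str] | None = None) -> GeneSetCollection:
    """GMT: one set per line — set id, description, then member gene ids,
    all tab-separated."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno} has no member genes")
            sid, desc = parts[0], parts[1]
            if sid in sets:
                raise ValueError(f"{path}: duplicate set id {sid!r} (line {lineno})")
            sets[sid] = (desc, frozenset(g for g in parts[2:] if g))
    return GeneSetCollection(
        sets, background_size,
        frozenset(universe) if universe is not None else None,
    )


def hypergeom_enrich(query: list[str], sets: GeneSetCollection) -> EnrichmentTable:
    """Upper-tail hypergeometric enrichment with BH correction.

    Rows sorted by q-value, then p-value, then set id.
    """
    if not query:
        raise ValueError("query gene list is empty")
    q = set(query)
    if sets.universe is not None:
        outside = q - sets.universe
        if outside:
            warnings.warn(
                f"{len(outside)} query genes outside the background universe dropped"
            )
            q -= outside
        if not q:
            raise ValueError("no query gene lies in the background universe")
    n_query = len(q)
    if sets.background_size < n_query:
        raise ValueError(
            f"background size {sets.background_size} smaller than query size {n_query}"
        )
    rows = []
    for sid in sorted(sets.sets):
        desc, members = sets.sets[sid]
        k = len(q & members)
        # P(X >= k) for X ~ Hypergeom(M=background, K=set size, n=query size)
        p = float(hypergeom.sf(k - 1, sets.background_size, len(members), n_query))
        p = min(max(p, 0.0), 1.0)
        rows.append({"set_id": sid, "description": desc, "n_overlap": k, "p_value": p})
    qvals = bh_adjust([r["p_value"] for r in rows])
    for r, qv in zip(rows, qvals):
        r["q_value"] = qv
    rows.sort(key=lambda r: (r["q_value"], r["p_value"], r["set_id"]))
    return EnrichmentTable(rows)
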