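"""Expression-matrix I/O and the two gene-filtering stages.

The pipeline's universal input is a genes × samples matrix of normalized
FPKM values. Two filters precede network construction:

* a presence filter that removes "non-informative" genes expressed
  (value strictly positive and not missing) in too few samples, and
* selection of the most variable genes ranked by median absolute
  deviation (MAD), a robust dispersion measure.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "FilterReport",
    "read_expression_matrix",
    "write_expression_matrix",
    "presence_filter",
    "mad_select",
    "gene_mad",
]


@dataclass
class ExpressionMatrix:
    """Genes × samples real matrix with NaN marking missing entries.

    Missing is distinct from zero: a cell that could not be parsed as a
    number (e.g. ``NA`` or an empty field) is missing, a printed ``0`` is
    an observed zero.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # float array, shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Row-subset by boolean mask or integer index, order preserved."""
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx], list(self.sample_ids), self.values[idx]
        )


@dataclass
class FilterReport:
    """Bookkeeping for one filtering run (presence filter and/or MAD cut)."""

    n_input_genes: int
    n_after_presence_filter: int
    n_after_mad_selection: int
    presence_threshold: int | None = None
    mad_rank_cutoff: int | None = None
    per_gene_mad: dict[str, float] = field(default_factory=dict)
    per_gene_presence: dict[str, int] = field(default_factory=dict)
    retained: dict[str, bool] = field(default_factory=dict)

    def write_tsv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["gene_id", "presence_count", "mad", "retained"])
            for g in sorted(set(self.per_gene_mad) | set(self.per_gene_presence)):
                w.writerow(
                    [
                        g,
                        self.per_gene_presence.get(g, ""),
                        repr(self.per_gene_mad[g]) if g in self.per_gene_mad else "",
                        int(self.retained.get(g, False)),
                    ]
                )


def read_expression_matrix(path: str, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes × samples TSV: header row of sample ids, one gene per row.

    The first header field (above the gene-id column) is ignored.
    Non-numeric or empty cells become missing (NaN). Duplicate gene ids and
    ragged rows are hard errors.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        sample_ids = [h.strip() for h in header[1:]]
        gene_ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            gid = row[0].strip()
            if len(row) - 1 != len(sample_ids):
                raise ValueError(
                    f"{path}: row {lineno} has {len(row) - 1} values, "
                    f"expected {len(sample_ids)}"
                )
            if gid in seen:
                raise ValueError(f"{path}: duplicate gene identifier {gid!r}")
            seen.add(gid)
            gene_ids.append(gid)
            vals = []
            for cell in row[1:]:
                try:
                    vals.append(float(cell))
                except ValueError:
                    vals.append(np.nan)
            rows.append(vals)
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_matrix(m: ExpressionMatrix, path: str, delimiter: str = "\t") -> None:
    """Write the matrix with full-precision (repr round-trip) values; NaN → ``NA``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["gene_id", *m.sample_ids])
        for gid, row in zip(m.gene_ids, m.values):
            w.writerow([gid, *("NA" if np.isnan(v) else repr(float(v)) for v in row)])


def _presence_counts(m: ExpressionMatrix) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.sum(np.nan_to_num(m.values, nan=0.0) > 0, axis=1)


def presence_filter(
    m: ExpressionMatrix, min_expressed_samples: int
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop genes expressed (> 0, non-missing) in ``min_expressed_samples``
    or fewer samples; retained genes have strictly more expressed samples.

    The study's convention for 92 tissues removes genes present in 46 or
    fewer samples, i.e. ``min_expressed_samples = n_samples // 2``.
    """
    if not 0 <= min_expressed_samples <= m.n_samples:
        raise ValueError(
            f"min_expressed_samples={min_expressed_samples} outside [0, {m.n_samples}]"
        )
    counts = _presence_counts(m)
    keep = counts > min_expressed_samples
    out = m.subset_genes(keep)
    report = FilterReport(
        n_input_genes=m.n_genes,
        n_after_presence_filter=out.n_genes,
        n_after_mad_selection=out.n_genes,
        presence_threshold=min_expressed_samples,
        per_gene_presence=dict(zip(m.gene_ids, (int(c) for c in counts))),
        retained={g: bool(k) for g, k in zip(m.gene_ids, keep)},
    )
    logger.info(
        "presence filter (>%d expressed samples): %d -> %d genes",
        min_expressed_samples, m.n_genes, out.n_genes,
    )
    return out, report


def gene_mad(values: np.ndarray) -> np.ndarray:
    """Per-row MAD = median(|x - median(x)|) over non-missing values.

    No consistency constant is applied; only the ranking is used. Rows with
    fewer than two non-missing values get MAD 0.
    """
    values = np.asarray(values, dtype=float)
    mads = np.zeros(values.shape[0])
    n_ok = np.sum(~np.isnan(values), axis=1)
    with np.errstate(all="ignore"):
        med = np.nanmedian(values, axis=1, keepdims=True)
        dev = np.abs(values - med)
        full = np.nanmedian(dev, axis=1)
    ok = n_ok >= 2
    mads[ok] = full[ok]
    if np.any(~ok):
        logger.info("%d genes with < 2 non-missing values: MAD set to 0", int(np.sum(~ok)))
    return mads


def mad_select(m: ExpressionMatrix, top_n: int) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep the ``top_n`` genes with largest MAD, original row order preserved.

    Ties at the boundary break by ascending gene identifier, so the
    selected set is deterministic across platforms.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if m.n_genes < 1:
        raise ValueError("matrix has no genes")
    mads = gene_mad(m.values)
    order = sorted(range(m.n_genes), key=lambda i: (-mads[i], m.gene_ids[i]))
    chosen = set(order[: min(top_n, m.n_genes)])
    keep = np.array([i in chosen for i in range(m.n_genes)])
    out = m.subset_genes(keep)
    report = FilterReport(
        n_input_genes=m.n_genes,
        n_after_presence_filter=m.n_genes,
        n_after_mad_selection=out.n_genes,
        mad_rank_cutoff=top_n,
        per_gene_mad=dict(zip(m.gene_ids, (float(v) for v in mads))),
        retained={g: bool(k) for g, k in zip(m.gene_ids, keep)},
    )
    logger.info("MAD selection (top %d): %d -> %d genes", top_n, m.n_genes, out.n_genes)
    return out, report
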