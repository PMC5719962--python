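"""Gene–gene similarity, soft thresholding and the scale-free criterion.

Similarity S is the biweight midcorrelation (bicor), a robust correlation
that downweights samples lying far from the per-gene median in MAD units.
With u_i = (x_i - med(x)) / (9 * MAD(x)) the sample weight is
w_i = (1 - u_i^2)^2 * 1[|u_i| < 1]; the weighted-centered vectors are then
correlated. Samples beyond 9 MADs from the median get weight zero, so a
single gross outlier cannot dominate the correlation the way it can for
Pearson. Genes with zero MAD have no defined envelope; pairs involving
them fall back to Pearson.

The adjacency is the unsigned soft threshold a_ij = |S_ij|^beta. The soft
power beta is chosen by the scale-free topology criterion: the smallest
power for which the log-log regression of connectivity frequency on
connectivity reaches a signed R^2 cutoff (0.8 by default). The fitted
degree-distribution exponent is a distinct quantity (gamma) even though
both are conventionally written as the exponent of a power law.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .expression import ExpressionMatrix, gene_mad

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "AdjacencyMatrix",
    "SoftThresholdScan",
    "bicor_matrix",
    "adjacency",
    "connectivity",
    "fit_powerlaw",
    "scale_free_fit",
    "pick_beta",
]


@dataclass
class SimilarityMatrix:
    gene_ids: list[str]
    S: np.ndarray  # symmetric, entries in [-1, 1]


@dataclass
class AdjacencyMatrix:
    gene_ids: list[str]
    A: np.ndarray  # symmetric, entries in [0, 1], zero diagonal
    beta: int


@dataclass
class SoftThresholdScan:
    """One row per candidate power: fit index and connectivity summaries."""

    rows: list[dict] = field(default_factory=list)  # beta, r2, slope, mean_k, median_k, max_k
    chosen_beta: int = 1

    def write_tsv(self, path: str) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["beta", "r2", "slope", "mean_k", "median_k", "max_k", "chosen"])
            for r in self.rows:
                w.writerow(
                    [
                        r["beta"],
                        repr(r["r2"]),
                        repr(r["slope"]),
                        repr(r["mean_k"]),
                        repr(r["median_k"]),
                        repr(r["max_k"]),
                        int(r["beta"] == self.chosen_beta),
                    ]
                )


def _masked_corr(num_rows: np.ndarray) -> np.ndarray:
    """Correlate rows of a centered (and possibly weighted) matrix whose
    missing entries are zeroed; rows of all zeros give zero correlation."""
    norms = np.sqrt(np.einsum("ij,ij->i", num_rows, num_rows))
    safe = np.where(norms > 0, norms, 1.0)
    unit = num_rows / safe[:, None]
    C = unit @ unit.T
    np.clip(C, -1.0, 1.0, out=C)
    return C


def bicor_matrix(m: ExpressionMatrix) -> SimilarityMatrix:
    """Biweight midcorrelation between all gene pairs.

    Missing samples get weight zero. Pairs where either gene has MAD 0
    fall back to Pearson (logged); genes with zero variance get similarity
    0 off-diagonal and 0 on the diagonal (no defined self-correlation).
    """
    if m.n_samples < 3:
        raise ValueError(f"need >= 3 samples for correlation, got {m.n_samples}")
    X = np.asarray(m.values, dtype=float)
    missing = np.isnan(X)

    with np.errstate(all="ignore"):
        med = np.nanmedian(X, axis=1, keepdims=True)
    mad = gene_mad(X)
    zero_mad = mad == 0

    centered = np.where(missing, 0.0, X - med)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = centered / (9.0 * mad[:, None])
    u[zero_mad] = 0.0
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    w[missing] = 0.0
    S = _masked_corr(centered * w)

    if np.any(zero_mad):
        logger.info(
            "%d genes with zero MAD: Pearson fallback for their pairs",
            int(np.sum(zero_mad)),
        )
        mean = np.where(
            np.sum(~missing, axis=1, keepdims=True) > 0,
            np.nanmean(np.where(missing, np.nan, X), axis=1, keepdims=True),
            0.0,
        )
        P = _masked_corr(np.where(missing, 0.0, X - mean))
        S[zero_mad, :] = P[zero_mad, :]
        S[:, zero_mad] = P[:, zero_mad]

    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    # constant genes: no dispersion, no unit self-similarity
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(np.where(missing, np.nan, X), axis=1)
    constant = ~(sd > 0)
    if np.any(constant):
        S[constant, :] = 0.0
        S[:, constant] = 0.0
    return SimilarityMatrix(list(m.gene_ids), S)


def adjacency(S: SimilarityMatrix, beta: int) -> AdjacencyMatrix:
    """Unsigned soft-threshold adjacency a_ij = |S_ij|^beta, zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be a positive integer")
    A = np.abs(S.S) ** beta
    np.fill_diagonal(A, 0.0)
    return AdjacencyMatrix(list(S.gene_ids), A, int(beta))


def connectivity(A: AdjacencyMatrix) -> np.ndarray:
    """Weighted connectivity k_i = sum_j a_ij (diagonal is zero by contract)."""
    return A.A.sum(axis=1)


def fit_powerlaw(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Binned log-log regression of the connectivity distribution.

    k is binned into ``n_bins`` equal-width bins; over non-empty bins,
    log10(frequency) is regressed on log10(mean k). Returns
    (signed r2, slope): r2 is negated when the slope is positive, so only
    decaying distributions can pass a positive cutoff. Degenerate inputs
    (all k equal, or < 2 usable bins) return (0.0, 0.0) with a warning.
    """
    k = np.asarray(k, dtype=float)
    if k.size < 2 or np.allclose(k, k[0]):
        warnings.warn("degenerate connectivity: scale-free fit undefined, returning 0")
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.full(n_bins, np.nan)
    freq = np.zeros(n_bins)
    for b in range(n_bins):
        sel = which == b
        if np.any(sel):
            mean_k[b] = k[sel].mean()
            freq[b] = np.sum(sel) / k.size
    ok = (freq > 0) & (mean_k > 0)
    if np.sum(ok) < 2:
        warnings.warn("fewer than 2 usable bins: scale-free fit undefined, returning 0")
        return 0.0, 0.0
    res = stats.linregress(np.log10(mean_k[ok]), np.log10(freq[ok]))
    r2 = float(res.rvalue**2)
    slope = float(res.slope)
    if slope > 0:
        r2 = -r2
    return r2, slope


def scale_free_fit(A: AdjacencyMatrix, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of the weighted connectivity distribution."""
    if A.A.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    return fit_powerlaw(connectivity(A), n_bins=n_bins)


def pick_beta(
    m: ExpressionMatrix,
    candidates: list[int] | None = None,
    r2_cutoff: float = 0.8,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan candidate soft powers and pick the smallest meeting the
    scale-free criterion.

    For each candidate the signed R^2 and connectivity summaries are
    recorded. If no candidate reaches ``r2_cutoff`` the candidate with the
    largest R^2 is chosen and a warning is raised.
    """
    if candidates is None:
        candidates = list(range(1, 21))
    if not candidates:
        raise ValueError("candidates must be non-empty")
    S = bicor_matrix(m)
    scan = SoftThresholdScan()
    for beta in sorted(candidates):
        A = adjacency(S, beta)
        k = connectivity(A)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2, slope = fit_powerlaw(k, n_bins=n_bins)
        scan.rows.append(
            {
                "beta": int(beta),
                "r2": r2,
                "slope": slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    passing = [r for r in scan.rows if r["r2"] >= r2_cutoff]
    if passing:
        scan.chosen_beta = passing[0]["beta"]
    else:
        best = max(scan.rows, key=lambda r: r["r2"])
        scan.chosen_beta = best["beta"]
        warnings.warn(
            f"no candidate beta reached signed R^2 >= {r2_cutoff}; "
            f"using beta={best['beta']} with R^2={best['r2']:.3f}"
        )
    logger.info("soft-threshold scan: chose beta=%d", scan.chosen_beta)
    return scan
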