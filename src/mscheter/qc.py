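"""Cell quality control, doublet scoring, normalization and scaling.

QC follows common droplet scRNA-seq practice: cells are dropped when
they express too few genes (low-quality libraries), too many genes
(likely doublets), carry too large a mitochondrial UMI share (damaged
cells), or receive a high doublet score.  All bounds are *strict*
inequalities — a cell sitting exactly on a threshold is retained.

Normalization divides each cell by its total UMI count and multiplies
by the median total across cells; scaling standardizes each gene to
mean 0 / variance 1 (unbiased, n-1) after an optional log1p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "compute_qc_metrics",
    "score_doublets",
    "filter_cells",
    "FilterReport",
    "normalize",
    "scale_genes",
]


def _row_totals(X) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray(X.sum(axis=1)).ravel()
    return np.asarray(X).sum(axis=1)


def compute_qc_metrics(adata: ad.AnnData, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell QC metrics: expressed genes, total UMI, mito fraction.

    ``doublet_score`` is initialised to NaN and filled by
    :func:`score_doublets`.  Zero-total cells get mito_fraction 0 and are
    logged.
    """
    if not mito_prefix:
        raise ValueError("mito_prefix must be non-empty")
    X = adata.X
    totals = _row_totals(X)
    if sparse.issparse(X):
        n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        n_genes = (np.asarray(X) > 0).sum(axis=1)
    mito_mask = np.asarray(adata.var_names.str.startswith(mito_prefix))
    mito_tot = _row_totals(X[:, mito_mask]) if mito_mask.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_tot / np.maximum(totals, 1), 0.0)
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.warning("%d cells have zero total UMI; mito_fraction set to 0", n_zero)
    return pd.DataFrame(
        {
            "n_expressed_genes": n_genes.astype(int),
            "total_umi": totals.astype(int),
            "mito_fraction": mito_frac,
            "doublet_score": np.nan,
        },
        index=adata.obs_names,
    )


def score_doublets(
    adata: ad.AnnData,
    expected_rate: float = 0.08,
    n_simulated_multiplier: float = 2.0,
    k_neighbors: int | None = None,
    n_pcs: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Doublet score per cell via simulated-doublet k-nearest neighbors.

    Synthetic doublets are formed by summing random pairs of observed
    cells; observed and simulated cells are embedded together by PCA of
    log1p counts (library size is deliberately kept as a signal, since a
    doublet carries roughly twice the UMIs of its parents), and each
    observed cell is scored by the fraction of simulated doublets among
    its k nearest neighbors, converted to a posterior doublet
    probability calibrated by ``expected_rate``.
    """
    n = adata.n_obs
    if k_neighbors is None:
        k_neighbors = max(3, round(0.5 * np.sqrt(n)))
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors ({k_neighbors}) must be < n_cells ({n})")
    if n < 2 * k_neighbors:
        raise ValueError("need at least 2*k_neighbors cells")
    rng = np.random.default_rng(seed)
    n_sim = int(round(n_simulated_multiplier * n))
    if n_sim < 1:
        logger.warning("n_simulated_multiplier too small; simulating 1 doublet")
        n_sim = 1
    X = adata.X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X)
    pa = rng.integers(0, n, size=n_sim)
    pb = rng.integers(0, n, size=n_sim)
    sim = X[pa] + X[pb]

    joint = np.log1p(np.vstack([X, sim]).astype(float))
    n_comp = min(n_pcs, joint.shape[0] - 1, joint.shape[1])
    emb = PCA(n_components=n_comp, random_state=seed).fit_transform(joint)

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    neigh = idx[:, 1:]  # drop self
    frac_sim = (neigh >= n).mean(axis=1)

    # convert neighbor fraction to doublet probability: among neighbors,
    # simulated cells occur at rate rho_sim; true doublets at expected_rate
    rho_sim = n_sim / n
    q = (frac_sim * k_neighbors + 1) / (k_neighbors + 2)  # smoothed
    ld = q * expected_rate / rho_sim
    score = ld / (ld + (1 - q))
    return np.clip(score, 0.0, 1.0)


@dataclass
class FilterReport:
    """Counts of cells violating each QC rule (a cell may violate several)."""

    n_input: int
    n_kept: int
    low_genes: int
    high_genes: int
    high_mito: int
    high_doublet_score: int
    predicted_doublets: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "low_genes": self.low_genes,
            "high_genes": self.high_genes,
            "high_mito": self.high_mito,
            "high_doublet_score": self.high_doublet_score,
            "predicted_doublets": self.predicted_doublets,
        }


def filter_cells(
    adata: ad.AnnData,
    metrics: pd.DataFrame,
    min_genes: int = 500,
    max_genes: int = 4000,
    max_mito: float = 0.10,
    max_doublet_score: float = 0.25,
    predicted_doublets: np.ndarray | None = None,
) -> tuple[ad.AnnData, FilterReport]:
    """Drop cells violating the QC rules; bounds are strict inequalities.

    Retains cells with ``min_genes <= n_expressed_genes <= max_genes``,
    ``mito_fraction <= max_mito`` and ``doublet_score <= max_doublet_score``
    (NaN doublet scores are treated as passing).  Raises if nothing
    survives.
    """
    if len(metrics) != adata.n_obs or not metrics.index.equals(adata.obs_names):
        raise ValueError("metrics must be indexed by the same cells as adata")
    g = metrics["n_expressed_genes"].to_numpy()
    m = metrics["mito_fraction"].to_numpy()
    d = metrics["doublet_score"].to_numpy(dtype=float)
    low = g < min_genes
    high = g > max_genes
    mito = m > max_mito
    dbl = np.nan_to_num(d, nan=0.0) > max_doublet_score
    pred = np.zeros(adata.n_obs, dtype=bool) if predicted_doublets is None \
        else np.asarray(predicted_doublets, dtype=bool)
    drop = low | high | mito | dbl | pred
    report = FilterReport(
        n_input=adata.n_obs,
        n_kept=int((~drop).sum()),
        low_genes=int(low.sum()),
        high_genes=int(high.sum()),
        high_mito=int(mito.sum()),
        high_doublet_score=int(dbl.sum()),
        predicted_doublets=int(pred.sum()),
    )
    if report.n_kept == 0:
        raise ValueError("all cells removed by QC filters")
    logger.info("QC filter: %s", report.as_dict())
    return adata[~drop].copy(), report


def normalize(adata: ad.AnnData) -> ad.AnnData:
    """Median-of-totals normalization.

    Each cell's counts are divided by its total UMI count and multiplied
    by the median total across all cells, preserving within-cell
    proportions exactly.  Zero-total cells stay all-zero and are logged.
    Returns a new AnnData with float ``X`` and ``uns['median_total']``.
    """
    totals = _row_totals(adata.X)
    if not (totals > 0).any():
        raise ValueError("no cell has positive total UMI count")
    median_total = float(np.median(totals))
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.warning("%d zero-total cells left all-zero by normalization", n_zero)
    scale = np.where(totals > 0, median_total / np.maximum(totals, 1e-300), 0.0)
    X = adata.X
    if sparse.issparse(X):
        Xn = sparse.diags(scale) @ X.astype(float)
        Xn = sparse.csr_matrix(Xn)
    else:
        Xn = np.asarray(X, dtype=float) * scale[:, None]
    out = ad.AnnData(X=Xn, obs=adata.obs.copy(), var=adata.var.copy(), uns=dict(adata.uns))
    out.uns["median_total"] = median_total
    return out


def scale_genes(norm: ad.AnnData, log_transform: bool = True) -> np.ndarray:
    """Standardize each gene across cells to mean 0, variance 1 (ddof=1).

    Applies log1p first by default.  Zero-variance genes become all-zero
    columns and are logged.  Returns a dense float array (cells x genes).
    """
    if norm.n_obs < 2:
        raise ValueError("scaling requires at least 2 cells")
    X = norm.X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float).copy()
    if log_transform:
        X = np.log1p(X)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        logger.info("%d zero-variance genes set to all-zero after scaling",
                    int(zero_var.sum()))
    sd_safe = np.where(zero_var, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, zero_var] = 0.0
    return Z
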