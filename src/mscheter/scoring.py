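"""Gene-program scoring and single-cell entropy.

``program_score`` is a module score with expression-matched controls:
genes are binned by mean expression, each program gene contributes the
difference between its expression and the mean of control genes drawn
from the same bin, and the per-cell average difference is Z-scored
across cells.  The control subtraction removes library-depth and
overall-expression effects; the Z-score makes scores comparable across
programs computed on the same cells.

``cell_entropy`` is the normalized Shannon entropy of a cell's UMI
distribution over genes,

    E_n = - sum_m p_{m,n} * log(p_{m,n} + 1e-10) / log(M),

with p_{m,n} the fraction of cell n's UMIs on gene m and M the number
of genes; natural log, zero-probability terms contribute 0.  E is ~0
for a cell expressing a single gene and ~1 for a uniform cell; lower
entropy proxies a more differentiated (less stem-like) state.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = ["program_score", "signature_score", "cell_entropy", "harmonize_genes"]


def harmonize_genes(genes, gene_index) -> list[str]:
    """Genes of a set present in the matrix, in set order; missing logged."""
    present = [g for g in genes if g in gene_index]
    missing = len(list(genes)) - len(present)
    if missing:
        logger.info("%d gene(s) of the set absent from the matrix; dropped", missing)
    return present


def program_score(
    norm: ad.AnnData,
    genes,
    n_bins: int = 30,
    n_control: int = 100,
    seed: int = 0,
    log1p: bool = True,
) -> np.ndarray:
    """Binned-control module score per cell, Z-scored across cells.

    All matrix genes are ranked by mean expression across cells and cut
    into ``n_bins`` equal-size bins (remainder in the last bin).  For
    each program gene, ``n_control`` control genes are sampled from its
    bin (with replacement when the bin is smaller).  The raw per-cell
    score is mean(program expression) - mean(control expression); the
    returned score is its Z-score across cells.
    """
    gene_index = {g: i for i, g in enumerate(norm.var_names)}
    present = harmonize_genes(genes, gene_index)
    if not present:
        raise ValueError("no program gene present in the matrix")
    if n_bins > norm.n_vars:
        raise ValueError("n_bins exceeds the number of genes")
    X = norm.X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    if log1p:
        X = np.log1p(X)
    rng = np.random.default_rng(seed)

    mean_expr = X.mean(axis=0)
    order = np.argsort(mean_expr, kind="stable")
    bin_size = norm.n_vars // n_bins
    bin_of = np.empty(norm.n_vars, dtype=int)
    for b in range(n_bins):
        hi = (b + 1) * bin_size if b < n_bins - 1 else norm.n_vars
        bin_of[order[b * bin_size:hi]] = b
    bins = [order[bin_of[order] == b] for b in range(n_bins)]

    prog_idx = np.array([gene_index[g] for g in present])
    control_cols = []
    for gi in prog_idx:
        pool = bins[bin_of[gi]]
        replace = len(pool) < n_control
        control_cols.append(rng.choice(pool, size=n_control, replace=replace))
    control_idx = np.concatenate(control_cols)

    raw = X[:, prog_idx].mean(axis=1) - X[:, control_idx].mean(axis=1)
    sd = raw.std(ddof=0)
    if sd == 0:
        logger.warning("constant raw program scores; returning zeros")
        return np.zeros(norm.n_obs)
    return (raw - raw.mean()) / sd


def signature_score(counts: ad.AnnData, genes) -> np.ndarray:
    """Percent of each cell's UMIs falling on the gene set (0-100).

    Zero-total cells score 0 and are logged.
    """
    gene_index = {g: i for i, g in enumerate(counts.var_names)}
    present = harmonize_genes(genes, gene_index)
    X = counts.X
    totals = np.asarray(X.sum(axis=1)).ravel() if sparse.issparse(X) else np.asarray(X).sum(axis=1)
    if not present:
        return np.zeros(counts.n_obs)
    idx = [gene_index[g] for g in present]
    sub = X[:, idx]
    in_set = np.asarray(sub.sum(axis=1)).ravel() if sparse.issparse(sub) else np.asarray(sub).sum(axis=1)
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.warning("%d zero-total cells scored 0", n_zero)
    with np.errstate(invalid="ignore"):
        return np.where(totals > 0, 100.0 * in_set / np.maximum(totals, 1e-300), 0.0)


def cell_entropy(counts: ad.AnnData) -> np.ndarray:
    """Normalized single-cell Shannon entropy in [0, 1] per cell.

    Zero-total cells get NaN (entropy undefined) and are logged; fewer
    than 2 genes is an error (log(M) = 0).
    """
    M = counts.n_vars
    if M < 2:
        raise ValueError("entropy requires at least 2 genes")
    X = counts.X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    totals = X.sum(axis=1)
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.warning("%d zero-total cells get NaN entropy", n_zero)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = X / np.maximum(totals[:, None], 1e-300)
        terms = np.where(p > 0, p * np.log(p + 1e-10), 0.0)
        ent = -terms.sum(axis=1) / np.log(M)
    ent[totals == 0] = np.nan
    return ent
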