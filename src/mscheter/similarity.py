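"""Neighbor-voting AUROC replicability of clusters across datasets.

MetaNeighbor-style: on a shared highly-variable gene set, build a
cell-cell Spearman-correlation network between the two datasets,
rank-normalize each cell's connectivities to [0, 1], and let each
cluster of the other dataset vote for every cell with its mean
normalized connectivity.  The AUROC of those votes for predicting a
cluster's own membership measures how well the two clusters pick out
the same cells: 0.5 is chance, 1 perfect replicability.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse, stats

logger = logging.getLogger(__name__)

__all__ = ["neighbor_voting_auroc", "top_variable_genes"]


def top_variable_genes(X, genes, n_top: int = 500) -> list[str]:
    """Gene names of the n_top most variable genes (variance of log1p)."""
    dense = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    v = np.log1p(dense).var(axis=0)
    order = np.argsort(v)[::-1][:n_top]
    return [genes[i] for i in order]


def _auroc(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUROC via the rank-sum identity U / (n1*n0), average ranks on ties."""
    n1 = int(positive.sum())
    n0 = len(scores) - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = stats.rankdata(scores)
    u = ranks[positive].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _vote_auroc(Xa, labels_a, Xb, labels_b) -> pd.DataFrame:
    """One direction: clusters of b vote for cells of a; AUROC per pair."""
    ra = np.apply_along_axis(stats.rankdata, 1, Xa)
    rb = np.apply_along_axis(stats.rankdata, 1, Xb)
    ra = (ra - ra.mean(axis=1, keepdims=True)) / np.maximum(ra.std(axis=1, keepdims=True), 1e-12)
    rb = (rb - rb.mean(axis=1, keepdims=True)) / np.maximum(rb.std(axis=1, keepdims=True), 1e-12)
    corr = ra @ rb.T / ra.shape[1]  # Spearman correlation a-cells x b-cells
    # rank-normalize each a-cell's connectivities to (0, 1]
    conn = np.apply_along_axis(stats.rankdata, 1, corr) / corr.shape[1]

    clusters_a = list(pd.unique(np.asarray(labels_a)))
    clusters_b = list(pd.unique(np.asarray(labels_b)))
    out = pd.DataFrame(np.nan, index=clusters_a, columns=clusters_b)
    for cb in clusters_b:
        mb = np.asarray(labels_b) == cb
        if mb.sum() < 2:
            logger.info("cluster %r has < 2 cells in dataset b; skipped", cb)
            continue
        votes = conn[:, mb].mean(axis=1)
        for ca in clusters_a:
            ma = np.asarray(labels_a) == ca
            if ma.sum() < 2 or ma.sum() == len(ma):
                logger.info("cluster %r degenerate in dataset a; skipped", ca)
                continue
            out.loc[ca, cb] = _auroc(votes, ma)
    return out


def neighbor_voting_auroc(
    norm_a,
    labels_a,
    norm_b,
    labels_b,
    hvg=None,
    n_hvg: int = 500,
    direction: str = "both",
) -> pd.DataFrame:
    """AUROC similarity matrix between clusters of two datasets.

    ``norm_a``/``norm_b`` are normalized AnnData objects.  ``hvg`` is an
    optional gene list; by default the union of each dataset's top
    ``n_hvg`` variable genes, intersected with the shared gene space,
    is used (at least 50 genes required).  ``direction`` 'a' scores
    dataset-a clusters from b's votes, 'b' the converse, 'both' (default)
    averages the two.  Rows are dataset-a clusters, columns dataset-b.
    """
    genes_a, genes_b = list(norm_a.var_names), list(norm_b.var_names)
    shared = [g for g in genes_a if g in set(genes_b)]
    if hvg is None:
        hv = set(top_variable_genes(norm_a.X, genes_a, n_hvg)) | \
            set(top_variable_genes(norm_b.X, genes_b, n_hvg))
        hvg = [g for g in shared if g in hv]
    else:
        hvg = [g for g in hvg if g in set(shared)]
    if len(hvg) < 50:
        raise ValueError(f"shared gene space too small ({len(hvg)} < 50)")
    ia = [genes_a.index(g) for g in hvg]
    ib = [genes_b.index(g) for g in hvg]
    Xa = norm_a.X[:, ia]
    Xb = norm_b.X[:, ib]
    Xa = Xa.toarray() if sparse.issparse(Xa) else np.asarray(Xa, dtype=float)
    Xb = Xb.toarray() if sparse.issparse(Xb) else np.asarray(Xb, dtype=float)

    if direction == "a":
        return _vote_auroc(Xa, labels_a, Xb, labels_b)
    if direction == "b":
        return _vote_auroc(Xb, labels_b, Xa, labels_a).T
    fwd = _vote_auroc(Xa, labels_a, Xb, labels_b)
    rev = _vote_auroc(Xb, labels_b, Xa, labels_a).T
    return (fwd + rev) / 2.0
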