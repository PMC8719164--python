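"""Weighted ligand-receptor crosstalk between cell subpopulations.

For each ordered subpopulation pair (source s, target t) and each
ligand-receptor pair (L, R) in the database, the contribution is

    max(0, log2FC_L(s vs rest)) * max(0, log2FC_R(t vs rest)) * ppi_prob,

included only when L is expressed in at least ``min_expr_fraction`` of
source cells and R in at least that fraction of target cells; the edge
weight s->t is the sum of contributions.  Only up-regulated ligands and
receptors signal (negative fold changes are floored at 0), so the
matrix is directed and non-negative.  Significance is assessed by a
label-permutation null per edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .de import DEFAULT_EPS

logger = logging.getLogger(__name__)

__all__ = ["InteractionMatrix", "interaction_weights", "significant_interactions"]


@dataclass
class InteractionMatrix:
    """Directed subpop x subpop crosstalk weights plus per-pair contributions."""

    weights: pd.DataFrame  # index = source, columns = target
    contributions: pd.DataFrame  # source, target, ligand, receptor, weight


def _group_stats(X, labels, clusters, eps):
    """Per-cluster one-vs-rest log2FC (floored later) and expressed fraction."""
    dense = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    total_mean = dense.mean(axis=0)
    n = dense.shape[0]
    lfc, frac = {}, {}
    for c in clusters:
        mask = labels == c
        nc = int(mask.sum())
        mean_in = dense[mask].mean(axis=0)
        mean_rest = (total_mean * n - mean_in * nc) / (n - nc)
        lfc[c] = np.log2((mean_in + eps) / (mean_rest + eps))
        frac[c] = (dense[mask] > 0).mean(axis=0)
    return lfc, frac


def interaction_weights(
    norm,
    labels,
    lrdb: pd.DataFrame,
    genes=None,
    min_expr_fraction: float = 0.1,
    eps: float = DEFAULT_EPS,
) -> InteractionMatrix:
    """Sum of weighted ligand-receptor paths between subpopulation pairs.

    ``norm`` is a normalized cells x genes matrix or AnnData; ``lrdb``
    has columns ligand / receptor / ppi_prob.  LR pairs whose genes are
    absent from the matrix are dropped (logged).
    """
    if hasattr(norm, "X"):
        genes = list(norm.var_names)
        X = norm.X
    else:
        X = norm
        if genes is None:
            raise ValueError("genes required when norm is a bare matrix")
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("labels must cover all cells")
    clusters = list(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("crosstalk needs at least 2 clusters")
    gidx = {g: i for i, g in enumerate(genes)}
    db = lrdb[lrdb["ligand"].isin(gidx) & lrdb["receptor"].isin(gidx)].reset_index(drop=True)
    dropped = len(lrdb) - len(db)
    if dropped:
        logger.info("%d LR pair(s) dropped after gene harmonization", dropped)

    lfc, frac = _group_stats(X, labels, clusters, eps)
    rows = []
    W = pd.DataFrame(0.0, index=clusters, columns=clusters)
    for _, pair in db.iterrows():
        li, ri = gidx[pair["ligand"]], gidx[pair["receptor"]]
        ppi = float(pair["ppi_prob"])
        for s in clusters:
            up_l = max(0.0, float(lfc[s][li]))
            if up_l == 0.0 or frac[s][li] < min_expr_fraction:
                continue
            for t in clusters:
                up_r = max(0.0, float(lfc[t][ri]))
                if up_r == 0.0 or frac[t][ri] < min_expr_fraction:
                    continue
                w = up_l * up_r * ppi
                W.loc[s, t] += w
                rows.append((s, t, pair["ligand"], pair["receptor"], w))
    contributions = pd.DataFrame(rows, columns=["source", "target", "ligand",
                                                "receptor", "weight"])
    return InteractionMatrix(weights=W, contributions=contributions)


def significant_interactions(
    norm,
    labels,
    lrdb: pd.DataFrame,
    genes=None,
    min_expr_fraction: float = 0.1,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[InteractionMatrix, pd.DataFrame]:
    """Permutation test for crosstalk edges.

    Cell labels are permuted ``n_permutations`` times; for each directed
    edge the empirical p is (1 + #{null >= observed}) / (1 + n_perm).
    Returns the observed matrix with sub-threshold edges zeroed, plus
    the per-edge p-value table.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    labels = np.asarray(labels)
    obs = interaction_weights(norm, labels, lrdb, genes=genes,
                              min_expr_fraction=min_expr_fraction)
    rng = np.random.default_rng(seed)
    exceed = pd.DataFrame(0, index=obs.weights.index, columns=obs.weights.columns)
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        null = interaction_weights(norm, perm, lrdb, genes=genes,
                                   min_expr_fraction=min_expr_fraction)
        null_w = null.weights.reindex(index=obs.weights.index,
                                      columns=obs.weights.columns).fillna(0.0)
        exceed += (null_w >= obs.weights).astype(int)
    pvals = (1 + exceed) / (1 + n_permutations)
    filtered = obs.weights.where(pvals < alpha, 0.0)
    return InteractionMatrix(weights=filtered, contributions=obs.contributions), pvals
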