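"""Shared-nearest-neighbor graph construction and community detection.

Cells are embedded by PCA of the scaled expression matrix; each cell's
k nearest neighbors (Euclidean, self excluded, distance ties broken by
index order) define its neighbor set, and any pair of cells whose sets
overlap is joined by an edge weighted by the Jaccard index
|shared| / |union| of the two sets.  Clusters are communities found by
greedy modularity maximization on the weighted graph.
"""

from __future__ import annotations

import logging

import igraph
import numpy as np
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = ["pca_embed", "build_snn_graph", "cluster_graph", "snn_cluster"]


def pca_embed(scaled: np.ndarray, n_pcs: int = 30, seed: int = 0) -> np.ndarray:
    """PCA embedding of a cells x genes scaled matrix."""
    n_comp = min(n_pcs, scaled.shape[0] - 1, scaled.shape[1])
    return PCA(n_components=n_comp, random_state=seed).fit_transform(scaled)


def build_snn_graph(scaled: np.ndarray, n_pcs: int = 30, k: int = 20,
                    seed: int = 0) -> sparse.csr_matrix:
    """Weighted SNN graph as a symmetric sparse matrix of Jaccard overlaps.

    ``scaled`` is cells x genes (or any feature matrix); PCA is applied
    first when the feature dimension exceeds ``n_pcs``.  Edge weights lie
    in (0, 1]: identical neighbor sets give 1, disjoint sets give no edge.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = scaled.shape[0]
    if k >= n:
        raise ValueError(f"k ({k}) must be < n_cells ({n})")
    emb = pca_embed(scaled, n_pcs, seed) if scaled.shape[1] > n_pcs else np.asarray(scaled, float)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    # drop self (first column once distances tie-break by index)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    A = sparse.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    A.data[:] = 1.0  # guard duplicate entries
    shared = (A @ A.T).tocoo()
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    w = s / (2 * k - s)
    W = sparse.csr_matrix((w, (r, c)), shape=(n, n))
    W = W + W.T
    return W


def cluster_graph(W: sparse.csr_matrix, seed: int = 0) -> np.ndarray:
    """Greedy modularity communities of a weighted graph.

    The agglomerative optimizer is deterministic; ``seed`` is accepted
    for interface stability.  Isolated vertices become singleton
    clusters.  Returns integer labels, one per vertex.
    """
    n = W.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    coo = sparse.triu(W, k=1).tocoo()
    if coo.nnz == 0:
        return np.arange(n)
    g = igraph.Graph(n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())),
                     edge_attrs={"weight": coo.data.tolist()})
    dendro = g.community_fastgreedy(weights="weight")
    clustering = dendro.as_clustering()
    labels = np.asarray(clustering.membership)
    logger.info("greedy modularity found %d clusters (modularity %.3f)",
                labels.max() + 1, g.modularity(labels, weights="weight"))
    return labels


def snn_cluster(scaled: np.ndarray, n_pcs: int = 30, k: int = 20,
                seed: int = 0) -> np.ndarray:
    """Convenience wrapper: SNN graph + greedy modularity labels."""
    return cluster_graph(build_snn_graph(scaled, n_pcs=n_pcs, k=k, seed=seed), seed=seed)
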