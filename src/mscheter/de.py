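"""Differential expression and over-representation analysis.

Between-group differences are tested gene-by-gene with the two-sided
Wilcoxon rank-sum (Mann-Whitney U) test: exact null distribution when
both groups have at most 50 cells and the gene has no ties, otherwise
the normal approximation with tie correction.  Effect size is
log2((mean_a + eps) / (mean_b + eps)) on normalized expression, and
multiple testing is controlled by Bonferroni over the genes tested.
A gene is called significant when |log2FC| >= 0.25 and adjusted
p < 0.01 (both configurable).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "differential_expression",
    "cluster_specific_genes",
    "overrepresentation",
    "wilcoxon_rank_sum",
]

EXACT_MAX_N = 50
DEFAULT_EPS = 1e-9


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum p for one gene; returns (U_a, p).

    Constant pooled data (all values identical) gives p = 1 by
    convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return len(a) * len(b) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)


def differential_expression(
    X,
    labels,
    group_a,
    group_b,
    genes=None,
    lfc_cutoff: float = 0.25,
    p_cutoff: float = 0.01,
    correction: str = "bonferroni",
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE between two groups of cells.

    ``X`` is a cells x genes normalized expression matrix, ``labels`` a
    per-cell group vector.  Returns a DataFrame indexed by gene with
    log2fc (a over b), p, adj_p, direction and a significance flag.
    """
    labels = np.asarray(labels)
    ia = np.flatnonzero(labels == group_a)
    ib = np.flatnonzero(labels == group_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("both groups need at least 2 cells")
    Xa = _dense(X[ia])
    Xb = _dense(X[ib])
    G = Xa.shape[1]
    if genes is None:
        genes = [f"g{i}" for i in range(G)]

    mean_a = Xa.mean(axis=0)
    mean_b = Xb.mean(axis=0)
    log2fc = np.log2((mean_a + eps) / (mean_b + eps))

    small = max(len(ia), len(ib)) <= EXACT_MAX_N
    if small:
        pvals = np.empty(G)
        for g in range(G):
            _, pvals[g] = wilcoxon_rank_sum(Xa[:, g], Xb[:, g])
    else:
        # vectorized asymptotic test with tie correction
        res = stats.mannwhitneyu(Xa, Xb, alternative="two-sided",
                                 method="asymptotic", axis=0)
        pvals = np.asarray(res.pvalue, dtype=float)
        const = (Xa == Xa[0]).all(axis=0) & (Xb == Xb[0]).all(axis=0) & (Xa[0] == Xb[0])
        if const.any():
            logger.info("%d constant genes set to p=1", int(const.sum()))
            pvals[const] = 1.0

    if correction == "bonferroni":
        adj = np.minimum(1.0, pvals * G)
    elif correction == "bh":
        adj = multipletests(pvals, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown correction {correction!r}")

    sig = (np.abs(log2fc) >= lfc_cutoff) & (adj < p_cutoff)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "adj_p": adj,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "significant": sig,
        },
        index=pd.Index(genes, name="gene"),
    )


def cluster_specific_genes(X, labels, target_cluster, genes=None, **kwargs) -> pd.DataFrame:
    """One-vs-rest DE; adds a ``specific`` flag = significantly up in target."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("cluster_specific_genes needs at least 2 clusters")
    if target_cluster not in uniq:
        raise ValueError(f"unknown cluster {target_cluster!r}")
    rest = np.where(labels == target_cluster, "__target__", "__rest__")
    df = differential_expression(X, rest, "__target__", "__rest__", genes=genes, **kwargs)
    df["specific"] = df["significant"] & (df["direction"] == "up")
    return df


def overrepresentation(gene_list, annotation: dict, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in annotated terms.

    ``annotation`` maps term name -> iterable of genes.  For each term
    the one-sided upper hypergeometric tail p is computed over
    ``universe``; q-values are Benjamini-Hochberg across terms.  Terms
    with no gene in the universe are skipped.
    """
    universe = set(universe)
    hits = set(gene_list)
    if not hits <= universe:
        raise ValueError("gene_list must be a subset of universe")
    N, n = len(universe), len(hits)
    rows = []
    for term, term_genes in annotation.items():
        K = len(set(term_genes) & universe)
        if K == 0:
            logger.info("term %r has no genes in universe; skipped", term)
            continue
        k = len(set(term_genes) & hits)
        p = stats.hypergeom.sf(k - 1, N, K, n)
        rows.append((term, k, K, float(p)))
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"]).set_index("term")
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q"] = []
    return df.sort_values("p")
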