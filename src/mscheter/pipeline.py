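"""End-to-end convenience pipeline: QC -> normalize -> cluster -> annotate.

Mirrors the standard per-sample workflow: score doublets, apply the QC
filters, median-normalize, scale, cluster the SNN graph, and assign each
cluster to the lineage program whose binned-control score it ranks
highest on — the programmatic analogue of annotating clusters by marker
gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .cluster import snn_cluster
from .qc import FilterReport, compute_qc_metrics, filter_cells, normalize, scale_genes, score_doublets
from .scoring import program_score

__all__ = ["ProcessedSample", "process_sample", "annotate_clusters"]


@dataclass
class ProcessedSample:
    """QC-filtered counts, normalized matrix, cluster and lineage labels."""

    counts: ad.AnnData
    norm: ad.AnnData
    qc_report: FilterReport
    cluster_labels: np.ndarray
    subpop_labels: np.ndarray  # cluster -> best-scoring program name


def annotate_clusters(norm: ad.AnnData, cluster_labels: np.ndarray,
                      programs: dict, seed: int = 0) -> np.ndarray:
    """Assign each cluster the program with the highest mean cell score."""
    scores = {name: program_score(norm, genes, seed=seed)
              for name, genes in programs.items()}
    mapping = {}
    for c in np.unique(cluster_labels):
        mask = cluster_labels == c
        mapping[c] = max(scores, key=lambda p: scores[p][mask].mean())
    return np.array([mapping[c] for c in cluster_labels])


def process_sample(adata: ad.AnnData, programs: dict | None = None,
                   expected_doublet_rate: float = 0.08, k: int = 20,
                   seed: int = 0) -> ProcessedSample:
    """Run QC, normalization, clustering and (optionally) annotation."""
    metrics = compute_qc_metrics(adata)
    metrics["doublet_score"] = score_doublets(adata, expected_rate=expected_doublet_rate,
                                              seed=seed)
    filtered, report = filter_cells(adata, metrics)
    norm = normalize(filtered)
    scaled = scale_genes(norm)
    clusters = snn_cluster(scaled, k=k, seed=seed)
    if programs is None:
        subpops = clusters.astype(str)
    else:
        subpops = annotate_clusters(norm, clusters, programs, seed=seed)
    return ProcessedSample(counts=filtered, norm=norm, qc_report=report,
                           cluster_labels=clusters, subpop_labels=subpops)
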