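"""Synthetic UMI count data with planted subpopulation structure.

The generator emulates the statistical features a droplet scRNA-seq
experiment on cultured mesenchymal stromal cells would show: a small
number of lineage-primed subpopulations, each marked by an up-shifted
"program" of lineage genes; log-normal library sizes; a fixed expected
share of mitochondrial UMIs; and a fraction of barcodes that are
doublets, i.e. exact sums of two singlet transcriptomes.  Ground truth
(subpopulation labels, doublet flags and parents, program gene sets) is
carried in ``obs``/``uns`` so downstream estimators can be tested for
parameter recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "simulate_counts", "simulate_induction_pair",
           "plant_qc_violations"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic scRNA-seq experiment.

    Defaults describe a modest 10x-style run: ~5k UMI per cell
    (log-normal), 5% mitochondrial UMIs spread over 10 MT- genes, an 8%
    expected doublet rate, and three subpopulations each carrying 50
    program genes up-shifted by one log2 unit (2-fold).
    """

    n_cells: int = 2000
    n_genes: int = 1500
    subpop_fractions: tuple[float, ...] = (0.5, 0.3, 0.2)
    program_genes_per_subpop: int = 50
    program_log2fc: float = 1.0
    libsize_log_mean: float = 8.5
    libsize_log_sd: float = 0.35
    mito_gene_count: int = 10
    mito_fraction_mean: float = 0.05
    doublet_rate: float = 0.08
    induction_shift: dict[str, float] | None = None
    induction_concentration: float = 1.0
    family: str = "multinomial"  # or "nb"
    nb_dispersion: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        fr = np.asarray(self.subpop_fractions, dtype=float)
        if fr.ndim != 1 or fr.size == 0 or (fr < 0).any():
            raise ValueError("subpop_fractions must be non-negative proportions")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"subpop_fractions must sum to 1, got {fr.sum()!r}")
        if not (0.0 <= self.doublet_rate < 1.0):
            raise ValueError("doublet_rate must be in [0, 1)")
        if self.program_genes_per_subpop <= 0:
            raise ValueError("program_genes_per_subpop must be positive")
        n_program = self.program_genes_per_subpop * fr.size
        if n_program + self.mito_gene_count > self.n_genes:
            raise ValueError(
                "program_genes_per_subpop x n_subpops + mito_gene_count "
                f"({n_program + self.mito_gene_count}) exceeds n_genes ({self.n_genes})"
            )
        if self.induction_concentration < 1.0:
            raise ValueError("induction_concentration must be >= 1")
        if self.family not in ("multinomial", "nb"):
            raise ValueError("family must be 'multinomial' or 'nb'")

    @property
    def subpop_names(self) -> list[str]:
        return [f"subpop{i}" for i in range(len(self.subpop_fractions))]


def _gene_ids(config: SimulationConfig) -> list[str]:
    n_reg = config.n_genes - config.mito_gene_count
    ids = [f"G{i:05d}" for i in range(n_reg)]
    ids += [f"MT-{i + 1}" for i in range(config.mito_gene_count)]
    return ids


def _profiles(config: SimulationConfig, rng: np.random.Generator,
              concentrated: str | None = None):
    """Per-subpopulation gene probability vectors plus the program map.

    All subpopulations share one log-normal baseline of gene weights;
    each subpopulation multiplies its own program genes by
    ``2**program_log2fc`` (times ``induction_concentration`` for the
    ``concentrated`` subpopulation).  Mitochondrial genes get a fixed
    share of the total weight so the expected mito fraction equals
    ``mito_fraction_mean`` in every subpopulation.
    """
    n_sub = len(config.subpop_fractions)
    n_reg = config.n_genes - config.mito_gene_count
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_reg)
    programs: dict[str, list[int]] = {}
    k = config.program_genes_per_subpop
    for i, name in enumerate(config.subpop_names):
        programs[name] = list(range(i * k, (i + 1) * k))

    profiles = np.empty((n_sub, config.n_genes))
    for i, name in enumerate(config.subpop_names):
        w = base.copy()
        fold = 2.0 ** config.program_log2fc
        if name == concentrated:
            fold *= config.induction_concentration
        w[programs[name]] *= fold
        if config.mito_gene_count > 0 and config.mito_fraction_mean > 0:
            mito_total = w.sum() * config.mito_fraction_mean / (1.0 - config.mito_fraction_mean)
            mito_w = np.full(config.mito_gene_count, mito_total / config.mito_gene_count)
        else:
            mito_w = np.zeros(config.mito_gene_count)
        full = np.concatenate([w, mito_w])
        profiles[i] = full / full.sum()
    return profiles, programs


def _draw_counts(rng: np.random.Generator, libsizes: np.ndarray, p: np.ndarray,
                 family: str, nb_dispersion: float) -> np.ndarray:
    if family == "multinomial":
        return np.vstack([rng.multinomial(n, p) for n in libsizes])
    # NB alternative: gene means lib * p, shared dispersion (var = mu + disp*mu^2)
    mu = libsizes[:, None] * p[None, :]
    r = 1.0 / nb_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    return rng.poisson(lam)


def simulate_counts(config: SimulationConfig) -> ad.AnnData:
    """Draw a UMI count matrix with planted subpopulations and doublets.

    Returns an :class:`~anndata.AnnData` (cells x genes, sparse integer
    ``X``) with ground truth in ``obs['subpop']``, ``obs['is_doublet']``,
    ``obs['doublet_parent1'/'doublet_parent2']`` (parent row indices, -1
    for singlets) and ``uns['programs']`` mapping subpopulation name to
    its program gene ids.  Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    profiles, programs = _profiles(config, rng)
    gene_ids = _gene_ids(config)

    n_doublets = rng.binomial(config.n_cells, config.doublet_rate)
    n_singlets = config.n_cells - n_doublets

    labels_idx = rng.choice(len(config.subpop_fractions), size=n_singlets,
                            p=np.asarray(config.subpop_fractions, dtype=float))
    libsizes = np.maximum(
        1, np.round(rng.lognormal(config.libsize_log_mean, config.libsize_log_sd,
                                  size=n_singlets)).astype(np.int64))
    counts = np.zeros((config.n_cells, config.n_genes), dtype=np.int64)
    for i in range(len(config.subpop_fractions)):
        mask = labels_idx == i
        if mask.any():
            counts[np.flatnonzero(mask)] = _draw_counts(
                rng, libsizes[mask], profiles[i], config.family, config.nb_dispersion)

    parent1 = np.full(config.n_cells, -1, dtype=np.int64)
    parent2 = np.full(config.n_cells, -1, dtype=np.int64)
    labels = np.empty(config.n_cells, dtype=object)
    names = config.subpop_names
    for j, i in enumerate(labels_idx):
        labels[j] = names[i]
    if n_doublets > 0:
        if n_singlets < 2:
            raise ValueError("too few singlets to form doublets")
        for d in range(n_doublets):
            a, b = rng.choice(n_singlets, size=2, replace=False)
            row = n_singlets + d
            counts[row] = counts[a] + counts[b]
            parent1[row], parent2[row] = a, b
            labels[row] = labels[a]  # label of first parent, flagged below

    is_doublet = np.zeros(config.n_cells, dtype=bool)
    is_doublet[n_singlets:] = True
    logger.info("simulated %d cells (%d doublets), %d genes",
                config.n_cells, n_doublets, config.n_genes)

    obs = pd.DataFrame(
        {
            "subpop": pd.Categorical(labels.astype(str)),
            "is_doublet": is_doublet,
            "doublet_parent1": parent1,
            "doublet_parent2": parent2,
        },
        index=[f"cell{i:05d}" for i in range(config.n_cells)],
    )
    adata = ad.AnnData(
        X=sparse.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=gene_ids),
    )
    adata.uns["programs"] = {k: [gene_ids[g] for g in v] for k, v in programs.items()}
    adata.uns["config"] = {"seed": config.seed, "n_cells": config.n_cells,
                           "n_genes": config.n_genes, "family": config.family}
    return adata


def simulate_induction_pair(config: SimulationConfig) -> tuple[ad.AnnData, ad.AnnData]:
    """Paired pre/post-induction datasets sharing gene programs.

    ``config.induction_shift`` maps subpopulation names to their
    post-induction fractions; the subpopulation with the largest fraction
    increase is treated as the induced lineage and, post-induction, has
    its expression concentrated onto its program genes by
    ``induction_concentration`` (>1 drives its per-cell entropy down,
    emulating differentiation).
    """
    if config.induction_shift is None:
        raise ValueError("induction_shift must be set for an induction pair")
    post_fr = np.array([config.induction_shift.get(n, 0.0) for n in config.subpop_names])
    if abs(post_fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"induction_shift fractions must sum to 1, got {post_fr.sum()!r}")

    pre = simulate_counts(replace(config, induction_shift=None))

    delta = post_fr - np.asarray(config.subpop_fractions)
    induced = config.subpop_names[int(np.argmax(delta))] if config.induction_concentration > 1 else None

    post_cfg = replace(config, subpop_fractions=tuple(post_fr),
                       induction_shift=None, seed=config.seed + 1)
    rng = np.random.default_rng(post_cfg.seed)
    # rebuild profiles with the *pre* seed so programs/baseline are shared,
    # then concentrate the induced subpopulation
    base_rng = np.random.default_rng(config.seed)
    profiles, programs = _profiles(post_cfg, base_rng, concentrated=induced)

    gene_ids = _gene_ids(post_cfg)
    n_doublets = rng.binomial(post_cfg.n_cells, post_cfg.doublet_rate)
    n_singlets = post_cfg.n_cells - n_doublets
    labels_idx = rng.choice(len(post_fr), size=n_singlets, p=post_fr)
    libsizes = np.maximum(
        1, np.round(rng.lognormal(post_cfg.libsize_log_mean, post_cfg.libsize_log_sd,
                                  size=n_singlets)).astype(np.int64))
    counts = np.zeros((post_cfg.n_cells, post_cfg.n_genes), dtype=np.int64)
    for i in range(len(post_fr)):
        mask = labels_idx == i
        if mask.any():
            counts[np.flatnonzero(mask)] = _draw_counts(
                rng, libsizes[mask], profiles[i], post_cfg.family, post_cfg.nb_dispersion)
    parent1 = np.full(post_cfg.n_cells, -1, dtype=np.int64)
    parent2 = np.full(post_cfg.n_cells, -1, dtype=np.int64)
    labels = np.array([post_cfg.subpop_names[i] for i in labels_idx], dtype=object)
    labels = np.concatenate([labels, np.empty(n_doublets, dtype=object)])
    for d in range(n_doublets):
        a, b = rng.choice(n_singlets, size=2, replace=False)
        row = n_singlets + d
        counts[row] = counts[a] + counts[b]
        parent1[row], parent2[row] = a, b
        labels[row] = labels[a]
    is_doublet = np.zeros(post_cfg.n_cells, dtype=bool)
    is_doublet[n_singlets:] = True

    obs = pd.DataFrame(
        {
            "subpop": pd.Categorical(labels.astype(str)),
            "is_doublet": is_doublet,
            "doublet_parent1": parent1,
            "doublet_parent2": parent2,
        },
        index=[f"postcell{i:05d}" for i in range(post_cfg.n_cells)],
    )
    post = ad.AnnData(X=sparse.csr_matrix(counts), obs=obs,
                      var=pd.DataFrame(index=gene_ids))
    post.uns["programs"] = {k: [gene_ids[g] for g in v] for k, v in programs.items()}
    post.uns["induced_subpop"] = induced if induced is not None else ""
    pre.uns["induced_subpop"] = induced if induced is not None else ""
    return pre, post


def plant_qc_violations(
    adata: ad.AnnData,
    n_low_genes: int = 0,
    n_high_genes: int = 0,
    n_high_mito: int = 0,
    n_high_doublet: int = 0,
    min_genes: int = 500,
    max_genes: int = 4000,
    mito_prefix: str = "MT-",
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Rewrite disjoint cells so each violates exactly one QC rule.

    Low-gene cells keep counts on ``min_genes - 100`` genes only;
    high-gene cells get one count on ``max_genes + 100`` genes (requires
    that many non-mito genes); high-mito cells have half their UMIs moved
    onto MT- genes.  High-doublet cells are only recorded here — their
    planted score (0.9) must be written into the QC metrics table by the
    caller, since doublet scores live there, not in the counts.  Counts
    are modified in place; returns {rule: planted cell indices} with key
    ``planted_doublet_score`` holding the score to assign.
    """
    rng = np.random.default_rng(seed)
    n_total = n_low_genes + n_high_genes + n_high_mito + n_high_doublet
    if n_total > adata.n_obs:
        raise ValueError("more planted violations than cells")
    chosen = rng.choice(adata.n_obs, size=n_total, replace=False)
    low = chosen[:n_low_genes]
    high = chosen[n_low_genes:n_low_genes + n_high_genes]
    mito = chosen[n_low_genes + n_high_genes:n_low_genes + n_high_genes + n_high_mito]
    dbl = chosen[n_low_genes + n_high_genes + n_high_mito:]

    mito_mask = np.asarray(adata.var_names.str.startswith(mito_prefix))
    non_mito = np.flatnonzero(~mito_mask)
    X = adata.X.tolil() if sparse.issparse(adata.X) else adata.X

    for i in low:
        keep = rng.choice(non_mito, size=max(1, min_genes - 100), replace=False)
        row = np.zeros(adata.n_vars)
        row[keep] = 1
        X[i] = row
    if n_high_genes and len(non_mito) <= max_genes + 100:
        raise ValueError("not enough genes to plant a high-gene violation")
    for i in high:
        on = rng.choice(non_mito, size=max_genes + 100, replace=False)
        row = np.zeros(adata.n_vars)
        row[on] = 1
        X[i] = row
    for i in mito:
        row = np.asarray(X[i].todense()).ravel() if sparse.issparse(adata.X) else X[i].copy()
        total = row.sum()
        row[mito_mask] = 0
        keep = row.sum()
        add = max(1, int(keep))  # mito UMIs ~= non-mito UMIs -> fraction ~0.5
        per = np.zeros(mito_mask.sum())
        per[: add % len(per)] = add // len(per) + 1
        per[add % len(per):] = add // len(per)
        row[mito_mask] = per
        X[i] = row
    if sparse.issparse(adata.X):
        adata.X = X.tocsr()
    return {
        "low_genes": low,
        "high_genes": high,
        "high_mito": mito,
        "high_doublet_score": dbl,
        "planted_doublet_score": np.full(len(dbl), 0.9),
    }
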