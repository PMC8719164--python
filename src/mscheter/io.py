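"""Reading and writing the plain-text exchange formats.

Counts travel as the 10x-style Matrix Market triplet (matrix.mtx +
genes.tsv + barcodes.tsv, genes x cells on disk) with an optional
metadata.tsv for per-cell annotations; gene sets as GMT; the
ligand-receptor database as a three-column TSV.
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

__all__ = ["write_mtx_dir", "read_mtx_dir", "read_gmt", "write_gmt",
           "read_lr_database", "write_lr_database"]


def write_mtx_dir(adata: ad.AnnData, path: str) -> None:
    """Write an AnnData as matrix.mtx (genes x cells) + genes/barcodes/metadata TSVs."""
    os.makedirs(path, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    scio.mmwrite(os.path.join(path, "matrix.mtx"), X.T.tocoo())
    pd.Series(adata.var_names).to_csv(os.path.join(path, "genes.tsv"),
                                      sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(os.path.join(path, "barcodes.tsv"),
                                      sep="\t", index=False, header=False)
    if adata.obs.shape[1]:
        adata.obs.to_csv(os.path.join(path, "metadata.tsv"), sep="\t")


def read_mtx_dir(path: str) -> ad.AnnData:
    """Read a matrix.mtx + genes.tsv + barcodes.tsv triplet (cells x genes)."""
    X = sparse.csr_matrix(scio.mmread(os.path.join(path, "matrix.mtx")).T)
    genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t", header=None)[0]
    barcodes = pd.read_csv(os.path.join(path, "barcodes.tsv"), sep="\t", header=None)[0]
    adata = ad.AnnData(X=X, obs=pd.DataFrame(index=barcodes.astype(str).tolist()),
                       var=pd.DataFrame(index=genes.astype(str).tolist()))
    meta_path = os.path.join(path, "metadata.tsv")
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        adata.obs = meta.loc[adata.obs_names]
    return adata


def read_gmt(path: str) -> dict[str, list[str]]:
    """GMT file -> {set name: gene list}; the description column is ignored."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_lr_database(path: str) -> pd.DataFrame:
    """TSV with columns ligand, receptor, ppi_prob -> validated DataFrame."""
    df = pd.read_csv(path, sep="\t")
    required = {"ligand", "receptor", "ppi_prob"}
    if not required <= set(df.columns):
        raise ValueError(f"LR database must have columns {sorted(required)}")
    prob = df["ppi_prob"].to_numpy(dtype=float)
    if ((prob < 0) | (prob > 1)).any():
        raise ValueError("ppi_prob must lie in [0, 1]")
    if df.duplicated(["ligand", "receptor"]).any():
        raise ValueError("duplicate ligand-receptor pairs")
    return df


def write_lr_database(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)
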