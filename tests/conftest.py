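import mscheter as m
import numpy as np
import pytest


@pytest.fixture(scope="session")
def small_dataset():
    """Three planted subpopulations, no doublets, modest size."""
    cfg = m.SimulationConfig(n_cells=600, n_genes=600, doublet_rate=0.0, seed=11)
    return m.simulate_counts(cfg)


@pytest.fixture(scope="session")
def small_norm(small_dataset):
    return m.normalize(small_dataset)


@pytest.fixture(scope="session")
def two_cluster_doublets():
    """Two well-separated subpopulations with an 8% doublet rate."""
    cfg = m.SimulationConfig(n_cells=800, n_genes=800,
                             subpop_fractions=(0.5, 0.5), seed=12)
    return m.simulate_counts(cfg)


def make_adata(counts, genes=None, cells=None):
    import anndata as ad
    import pandas as pd
    from scipy import sparse

    counts = np.asarray(counts)
    n, g = counts.shape
    genes = genes or [f"G{i}" for i in range(g)]
    cells = cells or [f"c{i}" for i in range(n)]
    return ad.AnnData(X=sparse.csr_matrix(counts.astype(float)),
                      obs=pd.DataFrame(index=cells),
                      var=pd.DataFrame(index=genes))
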