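"""Score lineage programs per cell and compute single-cell entropy.

The binned-control program score separates the subpopulation carrying
the program; the normalized Shannon entropy of each cell's UMI
distribution proxies its stemness (1 = maximally uncommitted).
"""

import mscheter as m
import numpy as np
from sklearn.metrics import roc_auc_score

cfg = m.SimulationConfig(n_cells=1000, n_genes=1500, doublet_rate=0.0, seed=2)
adata = m.simulate_counts(cfg)
norm = m.normalize(adata)

for name, genes in adata.uns["programs"].items():
    s = m.program_score(norm, genes, seed=2)
    in_pop = (adata.obs["subpop"] == name).to_numpy()
    auroc = roc_auc_score(in_pop, s)
    print(f"{name}: mean score in-pop {s[in_pop].mean():+.2f}, "
          f"out-of-pop {s[~in_pop].mean():+.2f}, AUROC {auroc:.3f}")
# Each program scores high exactly in its own subpopulation: these are
# the per-cell lineage-potential scores of a violin-plot comparison.

sig = m.signature_score(adata, adata.uns["programs"]["subpop0"])
print(f"signature score (% of UMIs on subpop0 program): "
      f"median {np.median(sig):.2f}")

e = m.cell_entropy(adata)
print(f"entropy: min {np.nanmin(e):.3f}, max {np.nanmax(e):.3f} "
      "(near 1 = transcriptome spread over many genes, stem-like)")
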