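# mscheter

Single-cell RNA-seq analysis of mesenchymal stromal cell (MSC)
heterogeneity, packaged as a tested, reusable Python library.

Cultured MSCs are not one cell type: samples from umbilical cord, bone
marrow, synovium or adipose tissue contain a small number of
lineage-primed subpopulations (chondrocyte-, osteocyte- and
adipocyte/myocyte-leaning), and an in-vitro induction expands the
subpopulation matching its direction while the others shrink and all
cells lose stemness.  `mscheter` implements the quantitative toolkit
such a study needs, end to end:

- **QC & doublets** — per-cell metrics; strict filters (retain cells
  with 500 ≤ expressed genes ≤ 4,000, mitochondrial UMI fraction ≤ 0.10,
  doublet score ≤ 0.25); a simulated-doublet kNN scorer calibrated by an
  expected doublet rate (default 0.08).
- **Normalization & scaling** — `x̃ᵢⱼ = xᵢⱼ / Σⱼxᵢⱼ · median(totals)`,
  then per-gene standardization (mean 0, variance 1, ddof = 1) of
  log1p values.
- **Clustering** — shared-nearest-neighbor graph in PCA space with
  Jaccard edge weights |N(i)∩N(j)| / |N(i)∪N(j)|, communities by greedy
  modularity maximization.
- **Differential expression** — two-sided Wilcoxon rank-sum per gene
  (exact for small tie-free groups), log₂ fold change of group means,
  Bonferroni correction; significant iff |log₂FC| ≥ 0.25 and adjusted
  p < 0.01.  One-vs-rest wrapper for cluster-specific genes, plus a
  hypergeometric over-representation test with BH q-values.
- **Program scores** — Tirosh-style module score: genes binned by mean
  expression into 30 equal bins, 100 expression-matched control genes
  per program gene, per-cell mean(program) − mean(control), Z-scored
  across cells.  Also a simple signature score (% of UMIs on a set).
- **Single-cell entropy** — normalized Shannon entropy
  `Eₙ = −Σₘ pₘₙ·log(pₘₙ + 10⁻¹⁰) / log(M)` with `pₘₙ` the fraction of
  cell *n*'s UMIs on gene *m*; a stemness proxy in [0, 1].
- **Cluster similarity** — MetaNeighbor-style neighbor-voting AUROC on
  a Spearman cell-cell network across datasets.
- **Crosstalk** — directed ligand-receptor weights
  `max(0, log₂FC_L(source)) · max(0, log₂FC_R(target)) · ppi_prob`,
  summed over an LR database, with a label-permutation significance
  test.
- **Pre/post comparison** — per-subpopulation Fisher's exact test of
  fraction shifts and rank-sum tests of score/entropy shifts.
- **Synthetic data** — a UMI generator (multinomial or negative
  binomial) planting subpopulations, lineage programs, log-normal
  library sizes, mitochondrial fractions, parent-sum doublets, QC
  outliers, and paired pre/post-induction designs with known fraction
  shifts and entropy decreases — every estimator above is validated
  against this ground truth.

## Worked example

`examples/05_induction_comparison.py` simulates a chondrogenesis-style
induction (the chondro-like subpopulation expands 67% → 91% and its
expression concentrates onto the lineage program), runs the full
pipeline on both arms, and tests the shifts:

```
         fraction_pre  fraction_post  odds_ratio  p_value stars
subpop
subpop0        0.6828         0.9156      5.0397   0.0000   ***
subpop1        0.1895         0.0000      0.0000   0.0000   ***
subpop2        0.1277         0.0844      0.6295   0.0002   ***
induced-subpop entropy: pre 0.9109 -> post 0.9075 (down, rank-sum p = 1.54e-20)
```

The pipeline's estimate of the induced subpopulation's post fraction
(0.916) recovers the planted 0.91; Fisher's exact test flags the
expansion and the compensating contractions; and the induced cells'
entropy drops significantly, the signature of lineage commitment.  The
other scripts in `examples/` demonstrate QC (01), clustering and marker
calling (02), program scores and entropy (03), and crosstalk plus
cross-dataset similarity (04), each printing the numbers it computes.

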