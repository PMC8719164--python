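# Methods

This note records the models, conventions and numerical choices behind
`mscheter`, and what the synthetic validation does and does not show.

## Synthetic data model

`simulate_counts` draws each cell's transcriptome from a
subpopulation-specific gene probability vector:

- A single log-normal baseline weight per gene (σ = 1) is shared by all
  subpopulations, so subpopulations differ only through their planted
  programs — the minimal structure under which clustering, marker
  calling and program scoring are meaningful.
- Each subpopulation multiplies its `program_genes_per_subpop` program
  genes (disjoint across subpopulations) by `2**program_log2fc`.
  Default 50 genes at log2FC = 1: a modest, realistic lineage-priming
  signal rather than a cell-type-level difference.
- Mitochondrial genes (named `MT-1…`, matching the 10x naming
  convention QC keys on) receive a fixed share of total weight so the
  expected mito fraction is `mito_fraction_mean` (default 0.05 —
  healthy cultured cells, safely below the 0.10 QC bound).
- Library sizes are log-normal (default mean 8.5, sd 0.35 on the log
  scale, ≈ 5,000 UMIs) and counts are multinomial given the library
  size, so each cell's total exactly equals its drawn library size.  A
  negative-binomial alternative (`family="nb"`, gamma-Poisson with
  shared dispersion) is available for over-dispersion checks.
- Doublets: the number of doublets is Binomial(n_cells, rate), default
  rate 0.08; each doublet is the exact element-wise sum of two distinct
  singlets drawn uniformly (hence both heterotypic and homotypic
  doublets occur), with parent indices recorded.
- `simulate_induction_pair` re-draws a post-induction arm with shifted
  subpopulation fractions from the same gene baseline and programs
  (same base seed); the subpopulation with the largest fraction gain is
  the induced lineage and its program weights are further multiplied by
  `induction_concentration` (≥ 1).  Concentrating probability mass onto
  few genes lowers the cells' normalized entropy, emulating
  differentiation.

All draws come from one `numpy` Generator seeded by `config.seed`, in a
fixed documented order, so identical configs give bit-identical counts.

What the generator does **not** emulate: batch effects, ambient RNA,
cell-cycle structure, gene-gene correlation beyond the program blocks,
tissue-specific expression magnitudes.  Passing tests therefore show
the estimators recover the structures they target under a clean
generative model — not that they are robust to every artifact of real
droplet data.

## QC and doublet scoring

Filter bounds are strict inequalities (a cell with exactly 4,000
expressed genes, 10% mito, or score 0.25 is retained); defaults
500 / 4,000 / 0.10 / 0.25.  Zero-total cells get mito fraction 0 and are
always removed via `min_genes`.  The filter report counts violations per
rule independently (a cell can violate several).

The doublet scorer simulates `n_simulated_multiplier × n` doublets
(minimum 1) by summing random observed-cell pairs, embeds observed and
simulated cells jointly by PCA (30 components) of **log1p raw counts** —
per-cell normalization is deliberately skipped so the roughly doubled
library size of a doublet remains a feature, which is what makes
homotypic doublets detectable at all — and scores each observed cell
from the smoothed fraction q of simulated doublets among its
k = round(0.5·√n) nearest neighbors, converted to a posterior
probability using the expected doublet rate ρ and the simulated
density: `score = (q·ρ/ρ_sim) / (q·ρ/ρ_sim + 1 − q)`.

## Normalization, scaling, clustering

Median-of-totals normalization preserves within-cell proportions
exactly; the median is taken over all cells.  Scaling standardizes each
gene with the unbiased (n−1) variance after log1p (log is on by
default; raw normalized values behave poorly under PCA).  Zero-variance
genes become all-zero columns.

The SNN graph uses each cell's k = 20 nearest PCA-space neighbors
(self excluded; distance ties broken by index order); any pair with
overlapping neighbor sets gets an edge weighted by the Jaccard index,
so weights lie in (0, 1].  Communities are found by greedy (CNM)
modularity maximization on the weighted graph — deterministic, no seed
sensitivity; the `seed` argument exists for interface stability.
Isolated vertices become singletons.

## Differential expression

Wilcoxon rank-sum, two-sided.  Exact null enumeration when both groups
have ≤ 50 cells and the gene has no ties; otherwise the normal
approximation with tie correction (verified against an exact
rank-assignment enumeration oracle to 1e-12 on small inputs).
log2FC = log2((mean_a + ε)/(mean_b + ε)) on normalized expression with
ε = 1e-9; the rank test itself is transform-invariant, so testing on
normalized rather than log values changes nothing.  Bonferroni
multiplies by the number of genes tested (capped at 1).  Constant genes
get p = 1 by convention.  Over-representation uses the one-sided upper
hypergeometric tail with BH q-values across terms.

## Program score and entropy

Program scoring bins all genes by mean expression (rank order, equal
bin sizes, remainder in the last bin; 30 bins) and samples 100 control
genes per program gene from its bin, with replacement when the bin is
smaller.  The per-cell raw score is mean(program) − mean(controls) on
log1p normalized expression; the reported score is its Z-score across
cells, which by construction has mean 0 / sd 1 and, thanks to the
expression-matched controls, negligible correlation with library size.
Z-scoring makes scores comparable across programs only when computed on
the same cells jointly.

Entropy follows the normalized Shannon form with the 1e-10 stabilizer
inside the logarithm and natural logs (the base cancels).  Consequences
worth knowing: a single-gene cell scores −log(1+1e-10)/log M ≈ −1e-10,
marginally below zero, so the [0, 1] bound is asserted with 1e-9 slack
on both ends; zero-count genes contribute exactly 0; zero-total cells
get NaN.  Entropy is invariant to gene order and to integer rescaling
of a cell's counts.

## Crosstalk and similarity

The LR edge weight multiplies the positive parts of the one-vs-rest
log2FCs of ligand (in the source) and receptor (in the target) by the
pair's PPI probability — only up-regulation signals, matching
non-negative summed-path edge displays — and requires the gene to be
expressed in ≥ 10% of the relevant cluster's cells (standard guard
against zero-inflation; configurable).  Multi-step paths through a PPI
graph and multi-subunit complexes are out of scope.  Significance is a
per-edge label-permutation test, p = (1 + #{null ≥ obs})/(1 + n_perm),
so a zero observed weight yields p = 1 and the smallest attainable p is
1/(n_perm + 1).

Neighbor-voting similarity builds a Spearman correlation network
between the cells of two datasets on the union of each dataset's top
500 variable genes (log1p variance), rank-normalizes each cell's
connectivities, lets each cluster of one dataset vote with its mean
connectivity, and computes the AUROC of those votes for the other
dataset's cluster memberships via the rank-sum identity.  Both voting
directions are computed and averaged by default (`direction='a'|'b'`
for one-way).  Being rank-based, the score is invariant under monotone
transforms of expression.

## Fraction-shift testing

Each subpopulation is tested with the two-sided Fisher's exact test on
its 2×2 membership × condition table, using the minimum-likelihood
convention (sum of all table probabilities ≤ the observed one) —
conventions differ across software, so this one is pinned by an
enumeration oracle in the tests.  The sample odds ratio (ad/bc) is
reported.  Significance stars default to * < 0.05, ** < 0.01,
*** < 0.001 and are configurable, since published figure legends are
not consistent about the convention.

## Problem sizes in the validation suite

The validation suite and `scripts/acceptance.py` use sizes at which the
planted effects are decisively detectable on a single CPU in minutes:
5,000 cells for QC recovery, 2,000 for doublet AUROC and program
scores, 3,000 for clustering ARI, 20 × (2,000 × 500) for DE null
calibration, 2,000 per arm for the induction mirror, and all canonical
2×2 tables with margins ≤ 30 for the Fisher oracle sweep (row
transposition covers the rest by symmetry).

## Known limitations

- Cross-sample integration/anchoring is not implemented; multi-sample
  clustering runs per sample or on naive concatenation.
- The doublet scorer's calibration assumes doublet profiles resemble
  observed-pair sums; intra-cluster (homotypic) doublets are separable
  mainly through library size, so its AUROC degrades if library-size
  variance is large relative to the doublet doubling.
- Embeddings for visualization (UMAP/t-SNE) are deliberately treated as
  replaceable plumbing with no numerical contract.
- Star maps, HVG counts, log-before-scale, and the DE expression layer
  are documented defaults, not claims about any particular published
  workflow's unstated choices.
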