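# Methods

This note documents the models, statistics, and numerical conventions the
package implements, the choices made where the design was genuinely open,
and what the synthetic-data generators do and do not emulate.

## Cell gating

Raw marker intensities are variance-stabilized as `arcsinh(raw / cofactor)`
with cofactor 1.0 by default (the ion-count imaging convention; CyTOF
practice uses 5, and the value is configurable). Positivity thresholds are
fitted per marker on the transformed scale. The default method is Otsu's
criterion over a 256-bin histogram: the cut maximizing the between-class
variance `w0·w1·(µ0−µ1)²`. When the two modes are separated by an empty
valley, every cut inside the valley ties for the maximum; we return the
midpoint of the tied plateau, which places the threshold mid-valley instead
of hugging the lower mode. An empirical-quantile method is available as an
alternative. A constant marker yields its constant value with a warning —
positivity is strict (`transformed > threshold`), so every cell is then
negative.

Cell typing applies an ordered rule list; the first matching rule wins.
The default order resolves immune subtypes first (B: CD45+CD20+;
macrophage: CD45+CD68+; CD8 T: CD45+CD3+CD8+; CD4 T: CD45+CD3+CD4+; then
generic CD45+ as `immune`), then endothelial (CD31+), tumor (PanCK+), and
stromal (Collagen I+ **or** Vimentin+; an AND variant is available). The
ordering is the documented tie-break for multi-positive cells — a
CD4/CD8 double-positive T cell gates as CD8 T. Stromal cells are then
assigned a fibroblast subtype by the sign pattern over
(α-SMA, Collagen I, Vimentin, CD90):

| pattern | subtype |
|---|---|
| (−, +, −, +) | S1 |
| (+, +, −, +) | S2 |
| (+, +, +, +) | S3 |
| (−, +, +, +) | S4 |

All other 12 patterns, and all non-stromal cells, are `unassigned`.

## Spatial statistics

Each ROI is an isolated coordinate frame (a separate acquisition); no
distance crosses ROIs, and coordinates are assumed to be in µm. The
closest-distance map gives, per cell, the Euclidean distance to the nearest
cell of a target label in the same ROI, self excluded; it is undefined (not
zero) when the ROI holds no eligible target. Per-ROI mean closest distances
are reported for every ordered (source, target) label pair; the statistic
is deliberately asymmetric. For patient-level views we report both per-ROI
values and the unweighted cross-ROI mean.

Neighborhood windows contain one central cell plus its k−1 nearest same-ROI
neighbors (default k = 26, i.e. 25 neighbors). Distance ties at the window
edge are broken by ascending `cell_id`, making windows deterministic.
ROIs with fewer than k cells yield truncated windows with a logged warning.
Window composition vectors (fractions over labels) **include** the center —
a window is 26 cells; neighbor fractions pool only the 25 non-center
members, because the statistic of interest is the share of a type *among
the neighbors*. Neighborhood clustering is k-means on composition rows
(10 restarts, fixed seed, best inertia kept); the cluster count is
user-set.

## scRNA stage

QC drops cells with fewer than `min_genes = 200` detected genes or a
mitochondrial count share above `max_mito = 0.10` — both boundaries strict
on the removal side, so a cell with exactly 200 genes or exactly 10% mito
is kept — then drops genes detected in fewer than `min_cells = 3` of the
*remaining* cells, in that order. Mitochondrial genes are identified by the
`MT-` name prefix (configurable). Normalization is counts / cell total ×
10⁴ followed by log2(x+1); the linear normalized values are retained for
fold-change computation.

Differential expression is a two-sided Wilcoxon rank-sum per gene: normal
approximation with tie correction in general, exact enumeration of all
group assignments when n_A + n_B ≤ 12. The fold change is
`log2((mean_A + 1)/(mean_B + 1))` on linear normalized expression (log2 is
declared; the base is configurable in the sense that the threshold is
applied on this declared scale). BH adjustment runs across the tested genes
of one comparison only, and significance requires |log2FC| ≥ 0.25 and
adjusted p < 0.05. The subtype contrast defaults to one-vs-rest pooled
(S3 vs all other fibroblasts), configurable to pairwise.

The ligand–receptor test re-implements the documented statistic of
permutation-based interaction tools rather than wrapping one: for a pair
and ordered clusters (A, B) the score is
`(mean ligand in A + mean receptor in B) / 2` on the log-normalized matrix,
tested only when the ligand's expressed fraction in A and the receptor's in
B both reach 0.10. The null permutes cluster labels over all cells (jointly
for all tested triples); `p = (1 + #{null ≥ observed}) / (1 + n_perm)`
never returns 0. Budgets below 100 permutations are rejected.

## Spatial transcriptomics stage

Deconvolution fractions are consumed, never computed. A spot is labeled
tumor/FB/endothelial when that type's fraction strictly exceeds the region
threshold (default 0.60; a fraction of exactly 0.60 is `mixed`). Thresholds
≤ 0.5 are rejected because two types could then qualify simultaneously.
"Boundary" is defined on the array lattice: an FB spot with ≥ 1 adjacent
endothelial spot or vice versa, under square 4-adjacency by default
(8-adjacency and an even-row-offset hex 6-adjacency are available for
Visium-like layouts). A positive ligand–receptor call requires all three
criteria: the spot is on the FB/endothelial boundary, the pair is queryable
in the user-supplied database, and the spot expresses both genes — where
"expresses" defaults to a nonzero count (`min_count = 1`), the conventional
reading under UMI sparsity. The single-spot reading of co-expression is
implemented (ligand and receptor in the same spot); a directional
FB-side/endothelial-side variant is not.

## Enrichment scoring and survival

The single-sample enrichment score is a weighted Kolmogorov–Smirnov random
walk. Genes are ranked by expression descending, ties broken by gene
symbol; the gene at position i (top = 1) carries rank weight (N−i+1)^α with
α = 0.25 by default. Walking down the ranking, in-set positions add their
normalized rank weight, out-set positions add 1/(N − |set ∩ genes|), and
the score integrates the difference of the two cumulative walks over all N
positions. Worked example (α = 0, N = 4, set = the top gene): the in-set
step is 1, out-set steps are 1/3, and the summed differences
(1−0) + (1−1/3) + (1−2/3) + (1−1) give a score of 2. The statistic depends
on expression only through ranks, so any strictly monotone within-sample
transform leaves it unchanged. We implement this single-sample (ssGSEA-style)
variant as the scoring engine rather than a kernel-density variant: the
score is used only ordinally (high/low split), for which the rank-based
walk is fully specified and deterministic. Cohort scores are rescaled to
[−1, 1] by the maximum absolute score (logged); a single-sample cohort is
returned raw with a warning.

Signature construction takes the significant, upregulated DE genes as
candidates and ranks them with a gradient-boosted tree classifier (target
subtype vs the rest; max depth 3, 200 trees, learning rate 0.1, histogram
method, fixed seed) by total-gain importance, ties broken by gene symbol.
Training is in-sample by design — this is feature selection, not a
generalization claim.

Stratification splits at the median (score > median is `high`, ties go
low). Kaplan–Meier is the product-limit estimator with censored-at-t
subjects remaining at risk at t; the log-rank test is the unstratified
two-group form (hypergeometric expectation and variance per event time,
χ² with 1 df, two-sided). Both are implemented directly and cross-checked
in the test suite against lifelines on random cohorts to 1e-10.

## Synthetic data: what it emulates, and what it does not

`gen_imc_rois` scatters ~10 cell classes (tumor, endothelial, four immune
classes, fibroblast subtypes S1–S4) uniformly in square ROIs, with
largest-remainder apportionment so per-type counts are within 1 of the
configured proportions. The planted proximity structure is parent–offspring
(Thomas-like): each S3 cell is placed uniformly in a disk of radius 20 µm
(default) around a random endothelial cell of its ROI — the simplest model
with a single interpretable radius. Marker intensities are two-mode
log-normals (positive mode meanlog log 20, negative log 0.5, sdlog 0.35):
right-skewed, strictly non-negative, and bimodal across +/− populations
like ion-count data, separated well enough that gating truth recovery is
well-posed (positive rates ≥ 95%/≤ 5% are asserted in tests). The panel is
the 12 gating-informative markers rather than a full 33-channel panel;
readers accept any panel.

`gen_scrna` draws negative-binomial counts (dispersion r = 10) with
genome-wide baseline means log-normal(0, 0.5); marker genes draw their
baseline from log-normal(log 2, 0.3) — markers are by definition reliably
detected genes — and are shifted by the planted log2 fold change in their
cluster. A 10-gene `MT-` block with unit mean provides a stable
mitochondrial share; designated cells can have their mitochondrial counts
inflated to an exact target share, or be thinned to a fixed number of
detected genes, to exercise both QC boundaries.

`gen_st` lays out a spot lattice (vertical split FB/endothelial by default)
with Dirichlet fractions concentrated on the true region (weight 0.8,
concentration 50 — true-region spots clear the 60% rule with high
probability, and concentration → ∞ recovers the layout exactly).
Ligand/receptor co-positivity is Bernoulli with rate 0.8 on the true
boundary and 0.05 elsewhere; a non-co-positive spot expresses at most one
of the two genes, so the planted rates are exact. Signature genes are
Poisson(5) in FB-region spots vs Poisson(0.3) elsewhere.

`gen_survival` draws exponential event times with rate
`0.1 · exp(β·z)` for standardized score z, and independent uniform
censoring on (0, m) with m solved numerically so the expected censored
share matches the requested rate — the simplest mechanism that keeps the
log-rank null exact.

None of the generators simulate segmentation noise, batch effects,
doublets, spot bleed-over, or real marker cross-talk. Passing tests
therefore demonstrate that the statistics recover the structure they are
defined to detect under their own model assumptions — not that those
assumptions hold in any particular tissue dataset.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use deliberately modest problem
sizes chosen to give the planted effects unambiguous power: 10 ROIs × 1000
cells (100 seeds) for spatial recovery, 100 vs 100 cells × 500 genes for
DE power, 500 simulated datasets for permutation-test calibration, 1000
simulations for log-rank null calibration, and 200-sample cohorts (50–100
replicates) for survival power. Every stochastic operation takes an
explicit seed, identical (configuration, seed) pairs reproduce outputs
exactly, and the acceptance script derives all sub-seeds from its single
`--seed` argument.

## Known limitations

* Gating quality depends on marker bimodality; Otsu thresholds degrade on
  unimodal or heavily skewed channels (the quantile method is the fallback).
* The ligand–receptor permutation test permutes labels globally and thus
  assumes exchangeability of cells across clusters under the null; strong
  per-cluster library-size differences would violate it (normalization
  mitigates this).
* The enrichment score is comparable only within one matrix; scores are
  rank-based and cohort-rescaled, not absolute quantities.
* Aggregation of per-ROI statistics to patient level is the unweighted
  cross-ROI mean; no mixed-effects modeling is attempted.
* The boundary definition is lattice-adjacency on array coordinates; it
  does not use physical distances and does not handle missing spots beyond
  treating absent coordinates as non-adjacent.
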