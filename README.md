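# leadedge

Spatially resolved analysis of the tumor microenvironment at the invasive
front ("leading edge") of muscle-invasive bladder cancer, built as a tested,
reusable pipeline:

* **Marker gating** of imaging-mass-cytometry (IMC) single-cell tables:
  arcsinh transformation, reproducible per-marker positivity thresholds
  (Otsu or quantile), ordered lineage rules, and the four-marker sign
  pattern that splits stromal fibroblasts (FB) into subtypes over
  (α-SMA, Collagen I, Vimentin, CD90):
  S1 (−,+,−,+), S2 (+,+,−,+), S3 (+,+,+,+), S4 (−,+,+,+).
* **Per-ROI spatial statistics**: mean closest Euclidean distance between
  cell types, 26-cell k-nearest-neighbor windows (one center + 25
  neighbors), window composition vectors, k-means neighborhood clustering,
  and pooled neighbor fractions.
* **scRNA stage**: QC (drop cells with < 200 detected genes or > 10%
  mitochondrial counts, then genes in < 3 cells), library-size
  log-normalization, two-sided Wilcoxon rank-sum differential expression
  with BH adjustment (significant when |log2FC| ≥ 0.25 and adjusted
  p < 0.05), and a cluster-label permutation ligand–receptor test with
  score (mean ligand in A + mean receptor in B)/2 and add-one p-values.
* **Spatial transcriptomics stage**: spot region labels from deconvolution
  fractions (> 60% rule), FB/endothelial boundary detection on the array
  lattice, three-criterion ligand–receptor colocalization calls
  (boundary ∧ queryable pair ∧ co-expression), and per-spot single-sample
  enrichment scores.
* **Prognostic signature**: DE candidates filtered by gradient-boosted-tree
  importance, a rank-based single-sample enrichment score per bulk sample
  (weighted Kolmogorov–Smirnov random walk, α = 0.25), median-split
  stratification, Kaplan–Meier curves, and the two-group log-rank test.

Because the matched IMC/scRNA/ST cohorts are not publicly deposited, the
package ships first-class synthetic-data generators that plant the exact
structure each stage is meant to detect — offspring-near-parent proximity
between the S3 fibroblast subtype and endothelial cells, bimodal log-normal
marker intensities, negative-binomial counts with known fold changes,
boundary-restricted ligand–receptor co-expression, and survival times with
log-hazard linear in a sample score — so every claim the pipeline makes is
testable against ground truth.

## Worked example

```python
import leadedge as le

cfg = le.ImcSimConfig(n_rois=4, cells_per_roi=800,
                      proximity_on=True, proximity_radius=20.0)
table, truth = le.gen_imc_rois(cfg, seed=11)

panel = list(cfg.panel)
t = le.transform_intensities(table, panel)
th = le.fit_thresholds(t, panel)            # Otsu per marker
t = le.gate_cell_types(t, th)               # ordered lineage rules
t = le.classify_fb_subtypes(t, th)          # S1-S4 sign patterns

d = le.roi_mean_distances(t, source_field="fb_subtype")
endo = d[d["target"] == "endothelial"]
print(endo.groupby("source")["mean_distance"].mean().round(1))

w = le.knn_windows(t, k=26)
for s in ("S1", "S2", "S3", "S4"):
    f = le.neighbor_fraction(w, t, s, "endothelial")
    print(f"{s}: {100*f:.2f}% of neighbors endothelial")
```

prints

```
source
S1            68.0
S2            63.8
S3            13.0
S4            61.4
unassigned    64.9
Name: mean_distance, dtype: float64
S1: 7.92% of neighbors endothelial
S2: 7.96% of neighbors endothelial
S3: 11.09% of neighbors endothelial
S4: 7.85% of neighbors endothelial
```

The planted structure is recovered: S3 fibroblasts sit ~13 µm from the
nearest endothelial cell versus ~60–70 µm for the other subtypes (the
generator placed each S3 cell within 20 µm of an endothelial parent), and
endothelial cells are over-represented among S3 neighbors relative to every
other fibroblast subtype.

The same stages are available from the shell:

```sh
leadedge simulate --kind imc --seed 11 --out out/sim
leadedge gate --cells out/sim/cells.tsv --markers CD45,CD20,... --out out/gated
leadedge spatial --cells out/gated/cells_labeled.tsv --out out/spatial
```

with further subcommands `de`, `lr-test`, `st-regions`, `st-coloc`,
`score`, and `survival`.

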