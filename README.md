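# scstability

Cold-ischemia stability assessment for droplet scRNA-seq tissue experiments.

When solid-tissue samples (lung, esophagus, spleen, …) are stored at 4 °C
between collection and dissociation, data quality can degrade: dying cells
shed RNA into the "soup", debris droplets accumulate, mitochondrial read
fractions rise, and intronic reads gain on exonic ones. `scstability` is a
library for quantifying these effects across a multi-donor, multi-tissue,
multi-time-point study design, with a synthetic droplet-experiment
generator that provides ground truth for every statistic it computes.

## What it computes

* **Droplet QC** — the depth-normalized UMI statistic
  ũ_b = u_b · 10⁶ / Σ u (values of a run sum to one million) and its
  three-way classification: ambient RNA (0, 0.25], debris (0.25, 5],
  cellular material (> 5); per-class means, paired/unpaired t contrasts
  across storage time, and ambient ("soup") gene profiles.
* **Cell QC** — exonic/intronic/intergenic read fractions and their
  quartile-extreme trends; the cell filter (300–5000 detected genes, 8000
  in esophagus, ≤ 20,000 UMIs, ≤ 10% mitochondrial reads, boundaries kept)
  with an exactly-reconciling removal log; genes kept when detected in ≥ 3
  cells per tissue; per-sample metric tables with BH-corrected trend tests.
* **Annotation transfer** — high-mitochondrial cells (excluded from
  clustering) reassigned to their nearest cell type by cosine similarity to
  log-normalized reference centroids, with abstention below 0.7.
* **Degradation statistics** — per-(tissue, cell type, time) mitochondrial
  fold-change tables with rank-test significance and strict masking (< 5
  cells ⇒ masked; absent sample ⇒ missing); cell-type composition tests
  over time (including a combined early-vs-72 h contrast) and one-way
  donor ANOVA; per-gene marginal R² variance partitioning; a cross-organ
  dendrogram (≤ 10 cells per stratum, 1000 most variable genes).
* **Expression comparisons** — pseudo-bulk construction, bulk vs
  pseudo-bulk and between-time-point differential expression via the
  Wilcoxon signed-rank test with BH correction and median log2 fold
  changes, per-cell-type storage signatures, and Fisher-exact overlap with
  a dissociation-stress gene list (FOS, FOSB, JUN, JUNB shipped).

## Worked example

`examples/03_mito_fold_change.py` generates one spleen donor at T0 and
72 h (~500 cells per cell type) in which T cells have their mitochondrial
UMI share doubled at 72 h, then recovers it:

```
cell_type  time_h  n_cells  fold_change     p_adj status stars
   B_cell       0      509            1         1     ok
   B_cell      72      504        0.997     0.578     ok
 Monocyte       0      490            1         1     ok
 Monocyte      72      497         1.01      0.56     ok
   T_cell       0      501            1         1     ok
   T_cell      72      499         1.99 1.76e-164     ok   ***
```

`fold_change` is mean mt% at t over mean mt% at T0 within a cell type; T0
rows are 1 by construction. Only the T-cell stratum at 72 h shows the
injected 2× inflation, at an adjusted p far below the \*\*\* display bin —
the other strata stay at their baseline, as they should under a cell-type
specific effect. The other examples walk through droplet classification,
boundary-exact cell filtering, bulk vs pseudo-bulk signature recovery, and
an end-to-end pipeline run (`scstability simulate` / `scstability run`
expose the same flow on the command line).

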