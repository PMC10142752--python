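# gliaquant

Single-cell microglial phenotyping from multiplexed immunohistochemistry.

Neurodegenerative diseases such as ALS change not only how many microglia a
tissue contains but which functional programs they run. Multiplexed
immunofluorescence panels measure five microglial functional proteins —
L-ferritin, HLA-DR, CD68, CD74 and Iba1 — together with pathology markers
(phosphorylated TDP-43 aggregates, astrocytic GFAP) on the same section.
`gliaquant` implements the full quantitative analysis for such panels, for
image analysts and neuropathology groups who need the numbers behind the
figures:

- **Mask-based quantification.** Per-marker binary masks from local-mean
  adaptive thresholding are combined into a microglial *master mask*
  (Iba1 ∪ HLA-DR ∪ CD68 ∪ CD74); each 8-connected component is one cell, and
  the mean intensity of every marker inside a cell approximates its protein
  concentration. Pathology load is the integrated pTDP-43 intensity inside a
  fixed-threshold ("clip") mask, normalised to the analysed ROI area, with
  optional removal of HLA-DR channel bleed-through; astrogliosis is the GFAP
  mask area fraction.
- **MOI^high gating.** For each marker of interest (MOI), a cutoff splits
  cells into high- and low-expressing; cutoffs are fitted on cells pooled
  across all cases (KDE-valley between log-intensity modes, an upper
  quantile, or a manual value). Per-case MOI^high percentages are the core
  phenotyping endpoints.
- **Cluster phenotyping.** Balanced per-subgroup subsampling, natural-log
  transform of the five intensities, Barnes–Hut t-SNE (learning rate
  N/12 tied to the early-exaggeration factor 12, applied for the first 250
  of 1000 iterations), a kNN graph with k = ⌊√N⌋ and Louvain community
  detection. Clusters are characterised by group contribution, per-case
  cluster percentages, and the *relative MOI^high percentage*
  rel(c, case, m) = pct_high(m | cluster c, case) − pct_high(m | case),
  whose case-weighted mean over clusters is identically zero.
- **Statistics.** Mann–Whitney U group comparisons (exact p for combined
  n ≤ 16, tie-corrected normal approximation otherwise) with the adaptive
  two-stage Benjamini–Krieger–Yekutieli FDR procedure at q = 0.01; Spearman
  correlation matrices with |r| > 0.7 flagged "very strong" (pTDP-43
  correlations suppressed in aggregate-free control groups); and for
  longitudinal mouse-style designs a Type-III two-way ANOVA with
  Bonferroni-adjusted per-timepoint contrasts.
- **A ground-truthed simulator.** Because such cohorts are rarely shareable,
  the `simulate` module generates cell tables and multi-channel tissue
  images with known truth: log-normal per-cell intensities with low/high
  modes per marker, latent phenotypes drawn from group-specific mixture
  fractions, disease severity co-scaling the CD68^high fraction and the
  pTDP-43 aggregate burden, astrocytic L-ferritin co-expression, and
  optional HLA-DR→pTDP-43 bleed-through. Every downstream stage is verified
  against this planted truth.

## Worked example

```python
import gliaquant as gq

# a default cohort: 10 control + 10 disease cases, two regions,
# 600 cells per case; disease severity co-scales CD68^high and pTDP-43 load
cfg = gq.default_cohort_config(n_cases=10, cells_per_case=600)
cells, truth = gq.generate_cell_table(cfg, seed=3)

thresholds = gq.fit_thresholds(cells)          # pooled KDE-valley cutoffs
flagged = gq.classify_moi(cells, thresholds)   # per-marker high/low flags
pct = gq.percent_high(flagged)                 # per-case MOI^high %

endpoints = pct.rename(columns={"marker": "endpoint", "pct_high": "value"})
res = gq.compare_groups(endpoints, q=0.01)
print(res[res.region == "motor_cortex"][
    ["endpoint", "median_control", "median_disease", "p_raw", "bky_discovery"]
].to_string(index=False))
```

Output:

```
  endpoint  median_control  median_disease    p_raw  bky_discovery
      CD68       10.416667       35.750000 0.000182           True
      CD74        9.916667       14.250000 0.000435           True
    HLA-DR        9.916667       14.166667 0.000577           True
      Iba1        9.583333        9.500000 0.761760          False
L-ferritin        4.666667       16.416667 0.000179           True
```

The disease motor cortex shows the planted elevations: %CD68^high rises
from ~10% to ~36%, L-ferritin^high and the HLA-DR^high/CD74^high pair rise
more modestly, and all four are discovered at FDR 0.01, while Iba1^high —
not shifted in the disease mixture — stays at its control level (p = 0.76,
not flagged).

The same analysis runs from the shell:

```bash
gliaquant all --out runs/demo --seed 3          # simulate → … → stats + manifest
gliaquant simulate --out runs/demo2 --seed 1    # single stage
```

with a YAML config (`--config`) controlling cohort size, thresholds,
embedding parameters and FDR level, and a `manifest.json` recording seeds,
package versions and output hashes.

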