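# Methods

This note documents the models and procedures `gliaquant` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make results
reproducible.

## The measurement model

A multiplexed immunofluorescence section yields one aligned 2D intensity
image per channel (the five microglial functional markers L-ferritin,
HLA-DR, CD68, CD74, Iba1; the pathology channels pTDP-43 and GFAP; a
nuclear counterstain) plus a manually drawn region of interest (ROI)
excluding folds and defects. Inputs are assumed pre-aligned across
labelling rounds; registration is out of scope.

Three quantification pipelines operate on these images:

**Pathology load.** High-immunoreactivity masks come from a fixed
("clip") threshold: `mask = pixels > t`. The pTDP-43 load is the
integrated intensity inside `mask ∩ ROI` divided by the ROI area in µm²;
astrogliosis is the GFAP mask area divided by ROI area (a fraction in
[0, 1]). Where the pTDP-43 channel carries residual cross-reactive HLA-DR
signal from an earlier round, pixels inside a high-HLA-DR clip mask are
set to zero before masking — a mask subtraction, not an arithmetic one,
because signal under confirmed bleed-through cannot be attributed to
pTDP-43 at all.

**Tissue-wide expression.** Each of Iba1, HLA-DR, CD68 and CD74 is
segmented with a local-mean adaptive threshold: a pixel is in the mask
when it exceeds the mean over a square window of side `window_um` by more
than `offset`. L-ferritin is excluded from segmentation because
astrocytes also express it; it is still *measured*. The per-marker masks
are unioned into the *master mask*; a marker's tissue-wide intensity is
its integrated intensity over `master ∩ ROI` per unit area. Both
normalisations in circulation — by ROI area (default) and by master-mask
area — are implemented and flag-selectable rather than silently picking
one.

**Single cell.** Every 8-connected component of `master ∩ ROI` with area
≥ `min_cell_area_px` is one cell; a cell's value for each marker is the
mean pixel intensity over its component, a proxy for per-cell protein
concentration. Objects touching the ROI border are kept; pixel
coordinates are 0-based (row, col).

Parameter defaults and rationale:

| parameter | default | why |
|---|---|---|
| adaptive window | 25 µm | about one microglial soma plus proximal domain; large enough to estimate local background, small enough to track illumination drift |
| adaptive offset | config-required (50 on the default synthetic scale) | sits between background noise excursions and the dimmest true soma; no universal value exists across stains |
| clip thresholds | config-required per channel | "high immunoreactivity" is a per-marker, per-dataset judgement |
| min cell area | 20 px at 0.5 µm/px (= 5 µm²) | discards soma fragments below a plausible microglial cross-section |
| connectivity | 8 | diagonal contact joins an object; the stricter 4-connectivity splits thin diagonal structures |

## MOI^high gating

For each marker of interest (MOI) a single cutoff is fitted on cells
pooled across **all** cases (fitting per case would let group differences
leak into the thresholds). Three methods:

- `valley`: Gaussian-KDE density of log intensity; the cutoff is the
  density minimum between the two most prominent modes. A mode counts
  only if its peak prominence is ≥ 2% of the tallest peak's density —
  real minority subpopulations at ≥ ~5% weight clear this comfortably
  while the micro-wiggles a KDE shows on unimodal data stay an order of
  magnitude below. With fewer than two such modes the method falls back
  to the 0.9 quantile with a warning and a `quantile_fallback`
  provenance tag.
- `quantile`: a stated upper quantile of the pooled intensities.
- `manual`: a pass-through for cutoffs read off density or XY scatter
  plots; this is the faithful representation of scatter-based manual
  gating, which is inherently interactive and is not re-implemented as an
  algorithm.

A cell is MOI^high when its mean intensity is **strictly** above the
cutoff; a cell exactly at the cutoff is low. The convention is arbitrary
but must be fixed for reproducibility. Per-case MOI^high percentages are
100 × high/total per (case, region, marker).

## Embedding and cluster phenotyping

Cells are subsampled to the same count per case-type/region subgroup so
each subgroup contributes equally, then the five intensities are
natural-log transformed (equal weighting; zeros get a pseudocount of 1
with a warning) with no further scaling. Barnes–Hut t-SNE (scikit-learn)
embeds to 2D with perplexity 250, learning rate N/EE, early exaggeration
EE = 12 during the first 250 of 1000 iterations, and PCA initialisation
for reproducible global geometry. Perplexity is reduced to (N−1)/3 with a
warning when the subsample is small. The Barnes–Hut backend fixes the
exaggeration phase at 250 iterations; a differing `ee_iterations` setting
warns rather than silently applying.

The kNN graph uses k = ⌊√N⌋ Euclidean neighbours per cell,
union-symmetrised, unweighted, with distance ties broken by index order
(exactly reproducible; verified against a brute-force oracle).
Communities come from igraph's Louvain (multilevel modularity,
resolution 1), relabelled contiguously from 1 by first occurrence;
modularity is reported. The cluster count is data-dependent and never
forced.

By default the graph is built on the 2D embedding — the reference
procedure for this analysis. A `cluster_on="features"` flag clusters the
5D log-intensity space instead. The two routes behave differently in a
way worth understanding: on a 2D embedding, a kNN graph is a geometric
planar-ish graph, and modularity maximisation splits any community larger
than roughly √(2·|E|) nodes (the resolution limit), so large homogeneous
phenotypes come out as several spatially contiguous sub-clusters — an
over-partition, not a failure, and consistent with embeddings of this
kind yielding dozens of clusters that are refinements of a few true
populations. On the 5D features the within-phenotype kNN graph is far
better connected and Louvain recovers well-separated planted phenotypes
essentially exactly (ARI ≈ 1 in the verification suite, vs ≈ 0.45 for the
embedding route on the same data). Cluster *composition* statistics are
valid on either route.

Composition tables: per-cluster group contribution (% of a cluster's
cells from each case group; rows sum to 100), per-case cluster
percentages (% of a case's cells in each cluster; sums to 100 per case),
and the relative MOI^high percentage

    rel(c, case, m) = pct_high(m | cluster c, case) − pct_high(m | case),

a difference in percentage points (not a ratio: the natural zero baseline
— "no enrichment" — only exists for subtraction). Its defining identity,
Σ_c w_c · rel(c) = 0 with w_c the case's cell share in cluster c, is
asserted in the test suite to 1e-9.

## Statistics

**Group comparisons.** Mann–Whitney U per endpoint; the exact
enumeration p is used when the combined sample is ≤ 16 and tie-free, the
tie-corrected normal approximation with continuity correction otherwise
(the cutover is a package choice; at 10-vs-10 cases the approximation
tracks the exact test closely). Families for multiplicity control follow
the figure-panel structure: all endpoints within one region are adjusted
together, with the family composition recorded in the output table.

**Two-stage FDR.** The adaptive two-stage linear step-up of Benjamini,
Krieger & Yekutieli at q = 0.01: stage 1 runs the linear step-up at
q′ = q/(1+q) and its rejection count r₁ estimates the true-null count
m₀ = m − r₁; stage 2 reruns the step-up at q′·m/m₀ (no discoveries if
r₁ = 0, all if r₁ = m). Implemented directly from the published
definition; the test suite checks flag-for-flag agreement with an
independent reference implementation on 1,000 random families, and that
the procedure is never less powerful than single-stage BH at the same q.
Because the group test is discrete at small n, the attainable
per-comparison level at α = 0.05 sits slightly below the nominal value
(≈ 0.043 at 10-vs-10); the calibration check accepts [0.03, 0.065].

**Correlations.** Pairwise-complete Spearman r (tie-corrected) with
two-sided p; |r| > 0.7 is flagged "very strong". Correlations with
pTDP-43 load are suppressed for control groups, which carry no
aggregates (a constant-zero load would make the coefficient undefined or
meaningless). Constant variables yield null entries with a warning.

**Longitudinal arm.** For genotype × timepoint designs: OLS with sum
contrasts and Type-III sums of squares (unbalanced cells allowed; an
empty cell is an error naming the cell), then per-timepoint genotype
contrasts using the pooled residual variance, with raw p multiplied by
the number of timepoints and capped at 1 (Bonferroni).

## The synthetic-data generator

The generator is first-class, tested code; it defines the conditions
under which every downstream claim is verified.

**Cell tables.** Each cell carries a latent *phenotype*: a binary
high/low assignment over the five markers (32 possible; named presets
cover pan-low, Iba1^high, HLA-DR^high CD74^high, CD68^high, and
L-ferritin^high CD68^high). Phenotypes are drawn per cell from
group-specific mixture fractions; marker mean intensities are log-normal
with the phenotype selecting the low or high log-mean per marker.
Log-normals were chosen because per-cell immunofluorescence intensity
distributions are strictly positive and right-skewed with long tails.
Disease is encoded as **shifted mixture fractions, not shifted modes**:
the working model is that tissue-wide increases reflect more
high-expressing cells, not brighter individual cells. A per-case severity
multiplier s ~ U(0.5, 1.5) in disease groups co-scales the CD68-containing
fractions (mass drawn from pan-low) and the pTDP-43 aggregate count,
planting the within-group covariation between %CD68^high and pathology
load; control groups keep baseline fractions and render no aggregates.

Defaults: low/high log-means 5.5/6.7 (modes ≈ 245/810) at log-sd 0.2 —
a 6-log-sd separation, comfortably bimodal — on a 16-bit-like scale;
control mixture 70% pan-low / 10% Iba1^high / 10% HLA-DR^high CD74^high /
5% CD68^high / 5% L-ferritin^high CD68^high; disease motor cortex 40/10/
15/20/15 (the +25-point CD68^high shift used in the power analysis);
disease hippocampus intermediate. These are package choices — the
underlying assay defines no canonical intensity scale or fractions — and
all are config-exposed.

**Images.** 1024×1024 px at 0.5 µm/px by default. Somata are uniform
disks (radius 5 µm) carrying the cell's drawn intensity per marker,
placed by rejection sampling with a 3 px edge gap so objects are
8-disconnected and counts are exact by construction; a request packing
more than 50% of the ROI raises a placement error. Astrocytes render
into GFAP and L-ferritin only; pTDP-43 aggregates are small bright blobs
(radius 3 px, intensity 5000) placed disjoint from somata; optional
bleed-through adds `coefficient × HLA-DR` into the pTDP-43 channel before
noise; every channel then gains N(background, noise²) with background 100
and noise 15 (≤ 10% of the dimmest cell mode), clipped at zero. The
planted truth records each cell's phenotype and intensities, per-case
MOI^high fractions (empirical over the drawn phenotypes, so recovery
error measures the pipeline, not binomial sampling), the painted pTDP-43
load, the GFAP area fraction, and all placements.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: no point-spread function or optical blur, no 3D
structure, no microglial processes or morphology (somata only), no
inter-round misalignment, no illumination gradients or vignetting, no
spatial clustering of cells or aggregates around pathology, no
cell-to-cell marker correlations beyond the discrete phenotype structure,
and uniform intensity within a soma. Recovery results certify the
pipeline's arithmetic and logic under the stated noise model, not
robustness to real-world optical artefacts.

## Numerical conventions and degenerate inputs

- All randomness flows through `numpy.random.default_rng(seed)`;
  identical (config, seed) reproduces tables bit-for-bit. Louvain is
  seeded through the `random` module that igraph consumes.
- Mask boundary conventions are strict (`>`), everywhere.
- An empty ROI is an error for every load measure; an empty mask is a
  valid zero. Zero-cell groups are omitted from percentage tables with a
  warning, and zero-cell cluster-case pairs are null, not zero.
- The adaptive-threshold local mean uses reflected boundaries; a window
  larger than the image is a parameter error.
- Verification problem sizes: mask/graph oracles run at 64²–200 elements,
  image recovery on 512² fields with 50–60 cells per case, clustering
  recovery at N = 4,000 over 3 seeds, calibration on 1,000 simulated
  families and power on 100 simulated cohorts of 10 + 10 cases × 300
  cells. These sizes give binomial/Monte-Carlo noise well inside the
  asserted tolerances while keeping the suite quick.

## Known limitations

- The MetaMorph operations the pipelines mirror ("threshold clip",
  "adaptive thresholding") are proprietary; the local-mean form here is
  the simplest operator consistent with their described behaviour, not a
  bit-level reproduction.
- Scatter-plot-based manual thresholding is represented by the `manual`
  method plus plot export; there is no algorithmic stand-in for the
  original interactive judgement.
- t-SNE coordinates are reproducible only within one library version;
  cluster *labels* and downstream composition statistics are seeded and
  stable given the embedding.
- The per-case aggregation over multiple fields per case defaults to an
  area-weighted mean and is config-exposed; cohort-level conventions
  (how many fields, which layers) are the user's responsibility.
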