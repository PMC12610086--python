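# Methods

This note documents the models and procedures implemented in
`trophipath`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the package's known
limitations.

## Analysis model

### Coordinates and calibration

All annotation geometry lives in pixel coordinates (origin top-left, y
down, 0-based, rings implicitly closed); physical quantities are
obtained through a per-slide `microns_per_pixel` calibration. Every
metric below is reported in physical units (µm, µm², %), so results are
independent of scanner magnification.

### Vessel morphometry

Vessel caliber is characterized by the mask area and by the Feret
diameters of the convex hull, computed by the rotating-calipers
construction. Both extrema are exact for polygons: the maximum Feret
diameter is the hull diameter (attained at a vertex pair, found by a
pairwise scan over hull vertices — annotation hulls have few vertices,
so the quadratic scan is preferred for robustness); the minimum Feret
diameter is the minimum width, which for a convex polygon is attained
perpendicular to some hull edge, so scanning edge normals is exhaustive.

Vessels are split into *small* and *large* at **300 µm² of mask area**,
the conventional boundary between capillaries and larger
venules/arterioles. A vessel exactly at the threshold counts as small
(strict inequality for large); the threshold is configurable
(`caliber_threshold_um2`). Area is used rather than a Feret-derived
equivalent-circle area because the threshold is stated in µm² of mask.

Compartment assignment is by centroid membership — *center* if the
centroid lies in a tumor polygon, *periphery* if in a peritumoral
polygon, *outside* otherwise. Centroid membership is deterministic and
robust for vessels straddling a boundary; overlap-fraction rules would
need a tie policy of their own. Relative area density divides the
summed area of tumor-center vessels by the tumor area only; peritumoral
vasculature is reported through the counts. Annotation masks in which
several vessels merge (shared adventitia) are treated as single
objects; no splitting heuristic is applied.

### Proliferation statistics

Tumor mitoses are binned on a square grid over the tumor bounding box
by floor division of their µm coordinates (a point exactly on a cell
edge belongs to the higher-index cell). The spatial-dispersion
statistic is Shannon entropy in base 10 over occupied cells,

    H = − Σ_{p_i>0} p_i · log10 p_i   (dits),

zero for an empty slide by convention, and bounded by log10 of the
number of tumor cells. The default cell size is **500 µm**; entropy is
only comparable across slides at a fixed cell size, and the parameter
is exposed everywhere (`grid_cell_um`).

Hot spots are occupied cells whose count reaches the 0.95 quantile of
occupied-cell counts and is at least 2 (an isolated mitosis is never a
hot spot); the perivascular fraction is the share of tumor mitoses
within 100 µm of the nearest vessel boundary. Neither the quantile nor
the radius has a published value; 0.95 marks the visually salient top
tier of cells, and 100 µm is a few capillary-to-cell diffusion lengths,
the scale at which "clustering around vessels" is biologically read.
Both are configurable.

### Heatmaps

The gradient heatmap is a Gaussian kernel density of object locations
(default bandwidth 250 µm on a 100 µm raster), normalized so the raster
integrates to the object count; boundary truncation loses kernel mass
only within a bandwidth of the edge. The segmented heatmap digitizes
per-cell counts at quantile breaks (defaults 0.5/0.75/0.9). Density is
of object locations, not of mask area; both map kinds render over the
region outlines to PNG with a fixed colormap, so identical inputs give
byte-identical files.

### Detection evaluation

Standard confusion bookkeeping: sensitivity tp/(tp+fn), specificity
tn/(tn+fp), precision tp/(tp+fp), F1 as the harmonic mean. Rows for
different hard-negative classes that share one positive set combine by
summing fp and tn and carrying tp/fn through. Mask overlap reports IoU
and Dice (two empty masks agree perfectly — the interobserver
convention); ROC-AUC is trapezoidal with rank-averaged ties; the
two-stage threshold sweep gates candidates on a detection score, then
counts positives by a classification score. Display rounding is
half-up to two decimals with raw values retained.

### Trophic-pattern classification

The five patterns summarize subtype-specific trophic behavior:
proliferative-vascular (micropapillary), hypoxic (solid), proliferative
(acinar), vascular (papillary), inactive (lepidic). The published
description of the patterns is qualitative; the decision rule here is
an explicit quantitative reconstruction with all constants in config:

1. **Necrosis override** — a slide with necrosis fraction ≥ 0.10 and
   relative density below the hypoxic centroid's density mean is
   hypoxic outright (necrosis with failing vasculature defines that
   pattern).
2. **Nearest centroid** — otherwise the slide's 8-field metric vector
   is standardized by the centroid table's pooled SDs (root mean square
   across patterns per field) and assigned to the Euclidean-nearest
   centroid; ties break by table order.

The packaged centroid means are the published per-subtype cohort values
for entropy, density, and the four counts; necrosis and perivascular
means are the expected values of the generative model below. The SD
column is a *standardization scale*, so it holds the within-pattern
per-slide dispersion of each metric: for counts and density this
coincides with the published cohort SDs (the generator reproduces
them), but for entropy the published cohort SDs (0.99–1.88 dits)
largely reflect between-case heterogeneity, while the per-slide
sampling spread of the statistic is ~0.03 dits; using the cohort value
would make the single most discriminative feature weightless. The
packaged entropy scale is 0.10 dits — several times the observed
per-slide spread, far below the cohort SD. Users classifying field data
with broader within-pattern entropy spread should raise it in
`centroids.yaml`.

## Synthetic cohort generator

The generator emulates the **annotation layer** of a five-subtype
adenocarcinoma cohort; each `SubtypeProfile` targets the published
per-subtype means/SDs of the six printed metrics. Cohort shape defaults
to 15 micropapillary + 84 solid + 13 papillary + 21 lepidic + 74 acinar
= 207 slides. All randomness flows from one seed (per-slide child
streams), so cohorts are byte-for-byte reproducible.

**Geometry.** The tumor is a low-order harmonically perturbed ellipse
scaled to exactly 1.5 × 10⁹ µm² (1500 mm²); the peritumoral band is the
same shape scaled by √2, so the annulus ring area equals the tumor area
exactly (the 1:1 design). Slides are 80 × 64 mm at 2 µm/px. The slide
scale is chosen so the tumor spans ~6000 analysis cells at the 500 µm
grid: the top of the published entropy range (3.59 dits) requires at
least 10^3.59 ≈ 3 900 occupied cells, so smaller geometries cannot
express it at this cell size.

**Counts.** Compartment-by-caliber vessel counts and the per-slide
mitosis budget are rounded lognormal draws moment-matched to the target
mean/SD. The printed count SDs rival or exceed the means; a Poisson
cannot represent that dispersion, and normal-based laws (truncated or
clipped at zero) either distort the mean or pile 13–14 % of their mass
at zero counts, which the data's positive means make implausible. A
zero SD degenerates to the rounded mean.

**Vessel sizes.** Small vessels draw log-uniform areas in (20, 300]
µm². Large tumor-center vessels are sized *conditionally*: a per-slide
density is drawn from the printed density mean/SD, and log-uniform
relative sizes (8:1 spread) are rescaled so the slide's total center
vessel area meets it, clipped to (300, 1.2 × 10⁶] µm². Independent size
draws cannot reproduce the printed density SDs — the count dispersion
alone would overdisperse density several-fold — so size and count are
negatively coupled, as the printed statistics jointly imply.
Peritumoral large vessels follow a per-subtype log-uniform law whose
scale is calibrated to the same density target. About 3 % of vessels
carry the lymphovascular-invasion flag, matching the cohort-level
prevalence of invasive vessels.

**Mitoses.** A mixture point process in the tumor: each point is
clustered with probability `clustering_weight` (2-D Gaussian, SD
150 µm, around one of `n_cluster_sites` hot-spot seeds) and uniform
otherwise. Seeds are anchored on the *walls* of randomly chosen tumor
vessels — anchoring on the boundary rather than the centroid keeps the
cluster beside the wall regardless of vessel size — and when a slide
has fewer tumor vessels than sites, the remainder are vessel-free
tumor locations, so the cluster count (hence the entropy level) does
not inherit the count dispersion. With no vessels at all the process
falls back to uniform with a warning. Site counts are 30
(micropapillary), 12 (solid), 10 (papillary), 12 (acinar), 5 (lepidic
— "singular" clusters; the 1.19-dit level requires few seeds).
Mitosis budgets (15 000 / 12 000 / 10 000 / 8 000 / 800 mean per slide)
scale with each subtype's proliferative activity and give every
subtype's entropy level enough support (an entropy of H dits needs at
least 10^H occupied cells).

**Entropy calibration.** `calibrate_clustering_weight` inverts the
monotone-decreasing entropy–weight curve by Monte-Carlo evaluation with
common random numbers; the packaged weights (0.1214, 0.268, 0.2767,
0.9777 and 0.7016 for micropapillary, solid, papillary, lepidic,
acinar) reproduce each entropy target to well within the 0.1-dit
calibration tolerance.

**Necrosis.** One or two disjoint elliptical blobs inside the tumor
with total area drawn from the profile's range — (0.10, 0.40) of the
tumor for the solid profile, (0, 0.05) otherwise.

**What the generator does not emulate.** Real tissue texture, stain
variation, and pixel data; irregular (non-annular) peritumoral bands;
correlations between metrics beyond the size–count coupling above
(profiles treat metrics as independent draws); within-subtype
between-case heterogeneity of the entropy level (the weight is fixed
per subtype, so generated entropy SDs are far below the published
cohort SDs); merged multi-vessel masks; and annotation noise. Passing
tests therefore demonstrate correctness of the estimators and the
internal consistency of the pipeline under the published cohort
statistics — not performance on real slides.

## Numerical choices and degenerate inputs

- Caliber ties (exactly 300 µm²) are small; hot-spot cells need ≥ 2
  mitoses; mitoses on grid lines go to the higher-index cell; empty
  slides yield 0 dits and zero density rather than errors.
- Zero denominators raise typed errors naming the metric (zero tumor
  area, single-class ROC labels, tp+fn = 0, ...); degenerate polygons
  (collinear, zero area) are rejected at validation.
- Two empty masks have IoU = Dice = 1.0.
- The region-balance check is advisory (report with a pass flag at
  tolerance 0.05); real annotations deviate from the 1:1 design and the
  pipeline proceeds.
- Cluster-point rejection sampling retries against the tumor polygon
  and falls back to uniform placement only in pathological geometries.
- The `confusion_fixture` inverse construction requires strictly
  positive thresholds whenever fn or tn is nonzero (a candidate can
  only fail a strictly positive gate).

## Problem sizes

The test suite analyzes a 250-slide synthetic cohort (50 per subtype)
for profile-recovery checks and reuses its first 15 slides per subtype
for pattern-recovery checks; geometry-oracle suites use 200 random
polygons against a 3600-direction scan. The acceptance script uses the
15-slide micropapillary cohort. These sizes put every Monte-Carlo
check's sampling error well below its tolerance while keeping a full
run in minutes on one CPU.

## Known limitations

- The trophic-pattern decision rule is a reconstruction; only the
  subtype ↔ pattern correspondence and the per-subtype metric
  statistics are published. Classifier constants (necrosis threshold,
  centroid scales, unprinted centroid fields) are package defaults, not
  published values.
- The published per-subtype statistics are mutually constraining in
  ways a single geometry cannot always satisfy (e.g. the entropy scale
  implies several thousand grid cells, while printed vessel counts and
  densities then require large-vessel areas well above 5 000 µm²); the
  generator resolves these tensions explicitly (large slides,
  conditional vessel sizing) and documents them here.
- Entropy in dits is grid-size dependent; cross-study comparisons
  require matching `grid_cell_um`.
- The GeoJSON dialect is this package's own (class/invasive/score under
  feature properties, calibration in a sidecar); exports from other
  annotation tools need a thin mapping layer.
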