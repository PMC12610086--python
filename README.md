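# trophipath

Spatial analysis of whole-slide image (WSI) annotation layers in lung
adenocarcinoma: vessel morphometry, mitotic-figure spatial statistics,
heatmaps, detection-evaluation metrics, and classification of tumors
into five **trophic patterns** — joint profiles of how a tumor feeds
(vascularization) and grows (proliferation).

The package is aimed at computational-pathology researchers who already
have annotation exports (vessel and region polygons, mitosis point
detections) and want reproducible downstream quantification without
touching raster pixel data. A seeded synthetic-cohort generator
emulates the annotation layer of a five-subtype adenocarcinoma cohort
so every stage is testable end to end.

## What it computes

For each slide (tumor region *T*, peritumoral band *P* designed at 1:1
area, vessel polygons *V*, mitosis points *M*):

- **Vessel morphometry** — per-vessel mask area *A* (µm²), minimum and
  maximum Feret diameters by rotating calipers on the convex hull
  (min width ⊥ a hull edge; max = hull diameter), caliber class
  (*small* if *A* ≤ 300 µm², else *large*), and compartment by centroid
  membership (center / periphery / outside).
- **Vessel census** — counts per compartment × caliber and the relative
  area density `100 · Σ A(center vessels) / area(T)` in %.
- **Mitoses entropy** — tumor mitoses binned on a 500 µm grid;
  `H = −Σ pᵢ log₁₀ pᵢ` over occupied cells, in **dits** (decimal
  digits). Low = clustered hot spots, high = diffuse proliferation.
  Plus hot-spot cells (count ≥ the 0.95 quantile of occupied cells,
  min 2) and the perivascular fraction (tumor mitoses within 100 µm of
  a vessel boundary).
- **Heatmaps** — segmented (quantile-break labels) and gradient
  (Gaussian kernel density) rasters, rendered as PNG over region
  outlines.
- **Evaluation metrics** — sensitivity/specificity/precision/F1 from
  confusion counts, per-hard-negative-class rows and their combination,
  IoU/Dice mask overlap, ROC-AUC, and a two-stage
  detection/classification threshold sweep.
- **Trophic patterns** — each slide's metric vector (entropy, density,
  four counts, necrosis fraction, perivascular fraction) is assigned to
  proliferative-vascular, hypoxic, proliferative, vascular, or inactive
  by a necrosis override plus nearest centroid in pooled-SD z-space.
  The packaged centroid table carries the published per-subtype cohort
  means.

## Worked example

```python
from trophipath.synthetic import GeneratorConfig, generate_cohort, load_profiles
from trophipath.pipeline import run_slide

profiles = load_profiles()
config = GeneratorConfig(seed=42, n_slides_per_subtype=3)
slides, manifest = generate_cohort(
    [profiles["micropapillary"], profiles["lepidic"]], config
)
for s in slides:
    v, table = run_slide(s)
    print(f"{s.calibration.slide_id}: entropy={v.entropy_dits:.2f} dits, "
          f"density={v.density_pct:.3f}%, "
          f"small/large center={v.n_small_center}/{v.n_large_center}, "
          f"perivascular={v.perivascular_fraction:.2f}, vessels={len(table)}")
```

prints

```
micropapillary_000: entropy=3.60 dits, density=0.073%, small/large center=23/5, perivascular=0.03, vessels=274
micropapillary_001: entropy=3.62 dits, density=0.025%, small/large center=14/9, perivascular=0.03, vessels=263
micropapillary_002: entropy=3.63 dits, density=0.041%, small/large center=43/14, perivascular=0.04, vessels=180
lepidic_000: entropy=1.18 dits, density=0.018%, small/large center=11/6, perivascular=0.44, vessels=54
lepidic_001: entropy=1.22 dits, density=0.032%, small/large center=8/13, perivascular=0.48, vessels=96
lepidic_002: entropy=1.21 dits, density=0.044%, small/large center=9/17, perivascular=0.37, vessels=168
```

Micropapillary slides show diffuse proliferation (entropy ≈ 3.6 dits,
the high end of the scale) with a rich vascular bed; lepidic slides
show a handful of perivascular mitotic clusters (≈ 1.2 dits, nearly
half of the mitoses within 100 µm of a vessel). Feeding these vectors
to `trophipath.patterns.classify_pattern` assigns
`proliferative_vascular` and `inactive` respectively.

## Command line

```bash
trophipath generate --seed 42 --out cohort/           # synthetic cohort (GeoJSON + sidecars)
trophipath analyze cohort/ --out analysis/            # per-slide metrics, summary, pattern calls
trophipath evaluate confusion.csv                     # sensitivity/specificity per negative class
trophipath render cohort/ micropapillary_000 --out maps/
```

Slides are interchanged as one GeoJSON FeatureCollection per slide
(`class` ∈ {tumor, peritumoral, vessel, mitosis, necrosis} under
feature properties; `invasive` and `score` where applicable) plus a
YAML calibration sidecar (`slide_id`, `width_px`, `height_px`,
`microns_per_pixel`).

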