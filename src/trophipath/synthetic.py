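"""Synthetic annotated-slide cohorts with subtype-specific structure.

Emulates the annotation layer of a lung-adenocarcinoma WSI cohort so
every pipeline stage is testable without image data.  Each histologic
subtype is parameterized by a :class:`SubtypeProfile` holding the target
mean/SD of the per-slide metrics (mitoses entropy in dits, vessel counts
per compartment and caliber, relative vessel area density, necrosis
fraction range).  A generated slide has:

* a blob-like tumor polygon (harmonically perturbed ellipse) and a
  surrounding annulus of exactly equal area (the 1:1 design);
* vessels placed uniformly per compartment, with counts drawn from
  rounded lognormals moment-matched to the profile's mean/SD (the
  printed dispersions exceed anything Poisson or truncated-normal can
  represent without distorting the mean); small vessels take
  log-uniform areas in (20, 300] µm², large tumor-center vessels are
  sized against a per-slide draw of the profile's density target, and
  large peritumoral vessels follow a per-subtype log-uniform law;
* mitoses from a uniform/clustered mixture point process: with
  probability ``clustering_weight`` a point belongs to a Gaussian
  cluster anchored on a tumor-vessel wall, otherwise it is uniform in
  the tumor.  The weight is calibrated (see
  :func:`calibrate_clustering_weight`) so the expected grid entropy at
  the default 500 µm cell matches the profile's entropy mean;
* necrosis blobs only where the profile's necrosis range calls for them.

Everything is driven by a seeded generator: a fixed seed reproduces a
cohort byte-for-byte.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import Point, Polygon

from .annotations import (
    AnnotatedSlide,
    MitosisAnnotation,
    RegionSet,
    SlideCalibration,
    VesselAnnotation,
    write_calibration,
    write_slide,
)
from .errors import ParameterError, ValidationError
from .evaluation import ConfusionCounts
from .proliferation import DEFAULT_GRID_CELL_UM, bin_mitoses, mitoses_entropy

#: Gaussian SD of a perivascular mitosis cluster, µm.
CLUSTER_SD_UM = 150.0
#: Log-uniform area range for small vessels, µm².
SMALL_VESSEL_AREA_UM2 = (20.0, 300.0)
#: Lower bound of the large-vessel area law, µm² (the caliber threshold).
LARGE_VESSEL_AREA_MIN_UM2 = 300.0
#: Fraction of vessels flagged as invasive (cohort-level LVI prevalence).
INVASIVE_RATE = 0.03


@dataclass(frozen=True)
class FieldStat:
    mean: float
    sd: float


@dataclass(frozen=True)
class SubtypeProfile:
    """Generator parameterization for one histologic subtype."""

    subtype: str
    pattern: str
    entropy_dits: FieldStat
    density_pct: FieldStat
    n_small_center: FieldStat
    n_small_periphery: FieldStat
    n_large_center: FieldStat
    n_large_periphery: FieldStat
    n_mitoses: FieldStat
    necrosis_fraction_range: tuple[float, float]
    clustering_weight: float
    n_cluster_sites: int
    n_slides: int


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generation parameters."""

    seed: int = 0
    slide_size_um: tuple[float, float] = (80_000.0, 64_000.0)
    microns_per_pixel: float = 2.0
    tumor_area_um2: float = 1.5e9
    grid_cell_um: float = DEFAULT_GRID_CELL_UM
    n_slides_per_subtype: int | None = None


# ---------------------------------------------------------------------------
# low-level geometry helpers


def _count_draw(stat: FieldStat, rng: np.random.Generator, size=None):
    """Rounded lognormal draw moment-matched to the target mean/SD.

    Count fields are over-dispersed (printed SDs rival or exceed the
    means), which a Poisson cannot represent and a zero-truncated or
    clipped normal can only represent by distorting the mean and piling
    probability mass at zero.  A lognormal with matching first two
    moments reproduces mean and SD exactly and keeps counts positive.
    A zero SD degenerates to the rounded mean.
    """
    if stat.sd <= 0:
        val = np.rint(max(0.0, stat.mean))
        return (np.full(size, val) if size is not None else val).astype(int) \
            if size is not None else int(val)
    if stat.mean <= 0:
        return np.zeros(size, dtype=int) if size is not None else 0
    sigma2 = math.log(1.0 + (stat.sd / stat.mean) ** 2)
    mu = math.log(stat.mean) - sigma2 / 2.0
    draw = rng.lognormal(mu, math.sqrt(sigma2), size=size)
    return np.rint(draw).astype(int) if size is not None else int(round(draw))


def _ellipse_polygon(
    cx: float, cy: float, area_px2: float, aspect: float, angle: float,
    n_vertices: int = 32,
) -> Polygon:
    """Ellipse-like polygon with exactly the requested polygon area."""
    # inscribed n-gon area deficit correction
    k = (n_vertices / (2 * math.pi)) * math.sin(2 * math.pi / n_vertices)
    a = math.sqrt(area_px2 * aspect / (math.pi * k))
    b = a / aspect
    t = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    ca, sa = math.cos(angle), math.sin(angle)
    return Polygon(np.column_stack([cx + ca * x - sa * y, cy + sa * x + ca * y]))


def _sample_in_polygon(
    poly: Polygon, n: int, rng: np.random.Generator, max_iter: int = 200
) -> np.ndarray:
    """Uniform points inside a polygon by vectorized rejection sampling."""
    if n <= 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    filled = 0
    for _ in range(max_iter):
        m = max(64, int(1.6 * (n - filled)))
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        keep = cand[shapely.contains_xy(poly, cand[:, 0], cand[:, 1])]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
        if filled == n:
            return out
    raise RuntimeError("rejection sampling failed to fill polygon")


# ---------------------------------------------------------------------------
# regions


def generate_regions(
    config: GeneratorConfig, rng: np.random.Generator
) -> RegionSet:
    """Blob-like tumor plus an equal-area surrounding annulus.

    The tumor is a harmonically perturbed ellipse scaled to exactly the
    configured tumor area; the peritumoral band is the same shape scaled
    by sqrt(2) about the center, so the annulus ring area equals the
    tumor area by construction (1:1 design).
    """
    mpp = config.microns_per_pixel
    w_px = config.slide_size_um[0] / mpp
    h_px = config.slide_size_um[1] / mpp
    cx, cy = w_px / 2.0, h_px / 2.0

    target_px2 = config.tumor_area_um2 / mpp**2
    aspect = w_px / h_px
    b0 = math.sqrt(target_px2 / (math.pi * aspect))
    a0 = aspect * b0

    # low-order harmonic perturbation of the radius, capped at ~10%
    amps = rng.uniform(0.01, 0.035, size=4)
    phases = rng.uniform(0.0, 2 * math.pi, size=4)
    t = np.linspace(0.0, 2 * math.pi, 256, endpoint=False)
    r = np.ones_like(t)
    for k, (amp, ph) in enumerate(zip(amps, phases), start=2):
        r += amp * np.cos(k * t + ph)
    inner_xy = np.column_stack([a0 * r * np.cos(t), b0 * r * np.sin(t)])

    # rescale to the exact tumor area
    tumor = Polygon(np.column_stack([cx + inner_xy[:, 0], cy + inner_xy[:, 1]]))
    s = math.sqrt(target_px2 / tumor.area)
    inner_xy *= s
    tumor = Polygon(np.column_stack([cx + inner_xy[:, 0], cy + inner_xy[:, 1]]))

    outer_xy = inner_xy * math.sqrt(2.0)
    shell = np.column_stack([cx + outer_xy[:, 0], cy + outer_xy[:, 1]])
    hole = np.column_stack([cx + inner_xy[:, 0], cy + inner_xy[:, 1]])
    annulus = Polygon(shell, holes=[hole])

    if not (annulus.bounds[0] >= 0 and annulus.bounds[1] >= 0
            and annulus.bounds[2] <= w_px and annulus.bounds[3] <= h_px):
        raise ValidationError("generated regions exceed slide bounds; "
                              "increase slide_size_um or reduce tumor_area_um2")
    return RegionSet(tumor=[tumor], peritumoral=[annulus])


# ---------------------------------------------------------------------------
# vessels


#: Ratio between the upper and lower bound of the large-vessel area law.
LARGE_VESSEL_AREA_SPREAD = 8.0


def large_vessel_area_range_um2(
    profile: SubtypeProfile, tumor_area_um2: float
) -> tuple[float, float]:
    """Bounds (a, 8a) of the large-vessel log-uniform area law.

    Calibrated so the expected total tumor-center vessel area matches
    the profile's relative-density target:
    density/100 × tumor area = E[n_small]·E[A_small] + E[n_large]·m,
    where m = a(c-1)/ln(c) is the mean of LogUniform(a, ca); solve for
    a, clamped to the caliber threshold from below.
    """
    lo, hi = SMALL_VESSEL_AREA_UM2
    mean_small = (hi - lo) / math.log(hi / lo)
    e_ns = profile.n_small_center.mean
    e_nl = profile.n_large_center.mean
    target_total = profile.density_pct.mean / 100.0 * tumor_area_um2
    m_req = (target_total - e_ns * mean_small) / max(e_nl, 1e-9)

    c = LARGE_VESSEL_AREA_SPREAD
    a = max(LARGE_VESSEL_AREA_MIN_UM2, m_req * math.log(c) / (c - 1.0))
    return a, c * a


#: Hard per-vessel cap on the large-vessel mask area, µm².
LARGE_VESSEL_AREA_CAP_UM2 = 1.2e6


def _large_center_areas_um2(
    profile: SubtypeProfile,
    n_large: int,
    small_total_um2: float,
    tumor_area_um2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Large tumor-center vessel areas conditioned on the density target.

    A per-slide density is drawn from the profile's printed mean/SD
    (clipped at 0); large-vessel areas get log-uniform relative sizes
    rescaled so the slide's total center vessel area meets it.  This
    conditional sizing reproduces the printed density dispersion, which
    independent size draws cannot (count SDs alone would overdisperse
    density several-fold).
    """
    if n_large == 0:
        return np.empty(0)
    d_slide = max(0.0, rng.normal(profile.density_pct.mean, profile.density_pct.sd))
    required = d_slide / 100.0 * tumor_area_um2 - small_total_um2
    shapes = np.exp(rng.uniform(0.0, math.log(LARGE_VESSEL_AREA_SPREAD), n_large))
    areas = shapes / shapes.sum() * max(required, 0.0)
    return np.clip(areas, LARGE_VESSEL_AREA_MIN_UM2 * 1.005,
                   LARGE_VESSEL_AREA_CAP_UM2)


def generate_vessels(
    profile: SubtypeProfile,
    regions: RegionSet,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[VesselAnnotation]:
    """Place vessels per compartment and caliber.

    Counts per compartment×caliber are round-then-clip normal draws of
    the profile's mean/SD; centers are uniform in the compartment
    polygon (eroded so the whole vessel stays inside).  Small vessels
    take log-uniform areas in (20, 300] µm²; large tumor-center vessels
    are sized against the profile's density target (see
    :func:`_large_center_areas_um2`); large peritumoral vessels follow
    the subtype's nominal log-uniform law.
    """
    mpp = config.microns_per_pixel
    counts = {
        ("center", "small"): int(_count_draw(profile.n_small_center, rng)),
        ("center", "large"): int(_count_draw(profile.n_large_center, rng)),
        ("periphery", "small"): int(_count_draw(profile.n_small_periphery, rng)),
        ("periphery", "large"): int(_count_draw(profile.n_large_periphery, rng)),
    }
    s_lo, s_hi = SMALL_VESSEL_AREA_UM2
    p_lo, p_hi = large_vessel_area_range_um2(profile, config.tumor_area_um2)

    areas: dict[tuple[str, str], np.ndarray] = {}
    areas[("center", "small")] = np.exp(
        rng.uniform(math.log(s_lo), math.log(s_hi), counts[("center", "small")])
    )
    areas[("center", "large")] = _large_center_areas_um2(
        profile, counts[("center", "large")],
        float(areas[("center", "small")].sum()), config.tumor_area_um2, rng,
    )
    areas[("periphery", "small")] = np.exp(
        rng.uniform(math.log(s_lo), math.log(s_hi), counts[("periphery", "small")])
    )
    areas[("periphery", "large")] = np.exp(
        rng.uniform(math.log(p_lo), math.log(p_hi), counts[("periphery", "large")])
    )

    vessels: list[VesselAnnotation] = []
    idx = 0
    for (compartment, caliber), area_arr in areas.items():
        n = len(area_arr)
        if n == 0:
            continue
        host = regions.tumor[0] if compartment == "center" else regions.peritumoral[0]
        # erode by the largest semi-axis present so vessels stay inside
        max_semi_px = math.sqrt(area_arr.max() * 2.5 / math.pi) / mpp
        eroded = host.buffer(-max_semi_px)
        if eroded.is_empty:
            eroded = host
        if eroded.geom_type != "Polygon":
            eroded = max(eroded.geoms, key=lambda g: g.area)
        centers = _sample_in_polygon(eroded, n, rng)
        aspects = rng.uniform(1.0, 2.5, n)
        angles = rng.uniform(0.0, math.pi, n)
        invasive = rng.random(n) < INVASIVE_RATE
        for i in range(n):
            poly = _ellipse_polygon(
                centers[i, 0], centers[i, 1], area_arr[i] / mpp**2,
                aspects[i], angles[i],
            )
            vessels.append(
                VesselAnnotation(id=f"v{idx:04d}", boundary=poly,
                                 invasive=bool(invasive[i]))
            )
            idx += 1
    return vessels


# ---------------------------------------------------------------------------
# mitoses


def _tumor_vessels(
    regions: RegionSet, vessels: Sequence[VesselAnnotation]
) -> list[VesselAnnotation]:
    if not vessels:
        return []
    cents = np.array(
        [[v.boundary.centroid.x, v.boundary.centroid.y] for v in vessels]
    )
    inside = np.zeros(len(cents), dtype=bool)
    for poly in regions.tumor:
        inside |= shapely.contains_xy(poly, cents[:, 0], cents[:, 1])
    return [v for v, keep in zip(vessels, inside) if keep]


def generate_mitoses(
    profile: SubtypeProfile,
    regions: RegionSet,
    vessels: Sequence[VesselAnnotation],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[MitosisAnnotation]:
    """Mixture point process of mitoses inside the tumor.

    Each of N points is clustered with probability ``clustering_weight``
    (Gaussian around one of ``n_cluster_sites`` hot-spot seeds, SD
    150 µm) and uniform in the tumor otherwise.  Seeds are anchored on
    the walls of randomly chosen tumor vessels (hot spots are typically
    perivascular, and anchoring on the boundary rather than the
    centroid keeps the cluster next to the wall regardless of vessel
    size); when the slide has fewer tumor vessels than sites, the
    remaining seeds are vessel-free locations uniform in the tumor, so
    the cluster count — and with it the entropy level — does not
    inherit the vessel-count dispersion.  Without any vessels the
    process falls back to uniform with a warning.
    """
    n_total = int(_count_draw(profile.n_mitoses, rng))
    if n_total == 0:
        return []
    tumor = regions.tumor[0]
    w = profile.clustering_weight
    tumor_vessels = _tumor_vessels(regions, vessels)
    if len(vessels) == 0 and w > 0:
        warnings.warn(
            f"{profile.subtype}: no vessels to seed clusters; "
            "falling back to a uniform point process",
            stacklevel=2,
        )
        w = 0.0
    n_clustered = int(rng.binomial(n_total, w)) if w > 0 else 0
    n_uniform = n_total - n_clustered

    pts = [_sample_in_polygon(tumor, n_uniform, rng)]
    if n_clustered > 0:
        k = profile.n_cluster_sites
        n_vessel_sites = min(k, len(tumor_vessels))
        anchors = []
        if n_vessel_sites:
            for vi in rng.choice(len(tumor_vessels), size=n_vessel_sites,
                                 replace=False):
                ring = tumor_vessels[vi].boundary.exterior
                p = ring.interpolate(rng.random() * ring.length)
                anchors.append([p.x, p.y])
        chosen = np.asarray(anchors).reshape(-1, 2)
        if n_vessel_sites < k:
            chosen = np.vstack(
                [chosen, _sample_in_polygon(tumor, k - n_vessel_sites, rng)]
            )
        sd_px = CLUSTER_SD_UM / config.microns_per_pixel
        remaining = n_clustered
        for _ in range(100):
            if remaining <= 0:
                break
            which = rng.integers(0, k, size=remaining)
            cand = chosen[which] + rng.normal(0.0, sd_px, size=(remaining, 2))
            keep = cand[shapely.contains_xy(tumor, cand[:, 0], cand[:, 1])]
            pts.append(keep)
            remaining -= len(keep)
        if remaining > 0:  # pathological geometry: fill uniformly
            pts.append(_sample_in_polygon(tumor, remaining, rng))

    xy = np.vstack(pts)
    scores = rng.uniform(0.65, 1.0, size=len(xy))
    return [
        MitosisAnnotation(location=Point(x, y), score=float(s))
        for (x, y), s in zip(xy, scores)
    ]


def generate_necrosis(
    profile: SubtypeProfile,
    regions: RegionSet,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[Polygon]:
    """Necrotic blobs inside the tumor, total area per the profile range."""
    lo, hi = profile.necrosis_fraction_range
    fraction = rng.uniform(lo, hi)
    tumor_px2 = regions.tumor[0].area
    total_px2 = fraction * tumor_px2
    if total_px2 <= 0:
        return []
    shares = [0.6, 0.4] if fraction > 0.15 else [1.0]
    blobs: list[Polygon] = []
    for share in shares:
        area = share * total_px2
        aspect = rng.uniform(1.0, 2.0)
        max_semi = math.sqrt(area * aspect / math.pi)
        host = regions.tumor[0].buffer(-max_semi)
        if host.is_empty:
            continue
        if host.geom_type != "Polygon":
            host = max(host.geoms, key=lambda g: g.area)
        for _ in range(20):
            c = _sample_in_polygon(host, 1, rng)[0]
            blob = _ellipse_polygon(c[0], c[1], area, aspect,
                                    rng.uniform(0, math.pi))
            if not any(blob.intersects(b) for b in blobs):
                blobs.append(blob)
                break
    return blobs


# ---------------------------------------------------------------------------
# slides and cohorts


def generate_slide(
    profile: SubtypeProfile,
    config: GeneratorConfig,
    slide_id: str,
    rng: np.random.Generator,
) -> AnnotatedSlide:
    """One fully annotated synthetic slide for a subtype."""
    mpp = config.microns_per_pixel
    calibration = SlideCalibration(
        slide_id=slide_id,
        width_px=int(round(config.slide_size_um[0] / mpp)),
        height_px=int(round(config.slide_size_um[1] / mpp)),
        microns_per_pixel=mpp,
    )
    regions = generate_regions(config, rng)
    vessels = generate_vessels(profile, regions, config, rng)
    necrosis = generate_necrosis(profile, regions, config, rng)
    mitoses = generate_mitoses(profile, regions, vessels, config, rng)
    return AnnotatedSlide(
        calibration=calibration,
        regions=regions,
        vessels=vessels,
        mitoses=mitoses,
        necrosis=necrosis,
        subtype_label=profile.subtype,
    )


def generate_cohort(
    profiles: Sequence[SubtypeProfile],
    config: GeneratorConfig,
    out_dir: str | Path | None = None,
) -> tuple[list[AnnotatedSlide], pd.DataFrame]:
    """Deterministic cohort of slides plus a manifest.

    ``config.n_slides_per_subtype`` overrides each profile's own cohort
    size; with the packaged profiles and no override the cohort has the
    study shape (15 micropapillary + 84 solid + 13 papillary +
    21 lepidic + 74 acinar = 207 slides).  With ``out_dir`` set, writes
    one GeoJSON per slide, a calibration sidecar YAML, and the manifest
    CSV.
    """
    if not profiles:
        raise ParameterError("need at least one profile")
    slides: list[AnnotatedSlide] = []
    rows = []
    index = 0
    for profile in profiles:
        n = config.n_slides_per_subtype or profile.n_slides
        for i in range(n):
            rng = np.random.default_rng([config.seed, index])
            slide_id = f"{profile.subtype}_{i:03d}"
            slides.append(generate_slide(profile, config, slide_id, rng))
            rows.append({"slide_id": slide_id, "subtype": profile.subtype,
                         "seed": config.seed, "stream": index})
            index += 1
    manifest = pd.DataFrame(rows, columns=["slide_id", "subtype", "seed", "stream"])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for slide in slides:
            write_slide(slide, out_dir / f"{slide.calibration.slide_id}.geojson")
        write_calibration([s.calibration for s in slides],
                          out_dir / "calibration.yaml")
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return slides, manifest


# ---------------------------------------------------------------------------
# entropy calibration


def expected_entropy(
    profile: SubtypeProfile,
    config: GeneratorConfig,
    clustering_weight: float,
    n_reps: int = 3,
    base_seed: int = 715,
) -> float:
    """Monte-Carlo estimate of the mean grid entropy at a given weight."""
    p = replace(profile, clustering_weight=float(clustering_weight))
    vals = []
    for rep in range(n_reps):
        rng = np.random.default_rng([base_seed, rep])
        slide = generate_slide(p, config, f"cal_{rep}", rng)
        vals.append(mitoses_entropy(bin_mitoses(slide, config.grid_cell_um)))
    return float(np.mean(vals))


def calibrate_clustering_weight(
    profile: SubtypeProfile,
    config: GeneratorConfig,
    tol_dits: float = 0.03,
    n_reps: int = 3,
    max_iter: int = 14,
) -> float:
    """Bisection on the (monotone decreasing) entropy–weight curve.

    Finds the clustering weight at which the expected grid entropy at
    the configured cell size matches the profile's entropy-mean target;
    clamps to 0 or 1 when the target lies outside the achievable range.
    """
    target = profile.entropy_dits.mean
    lo, hi = 0.0, 1.0
    e_lo = expected_entropy(profile, config, lo, n_reps)
    if e_lo <= target:
        return 0.0
    e_hi = expected_entropy(profile, config, hi, n_reps)
    if e_hi >= target:
        return 1.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        e_mid = expected_entropy(profile, config, mid, n_reps)
        if abs(e_mid - target) <= tol_dits:
            return mid
        if e_mid > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# fixture transforms


def butterfly_reflection(tile: np.ndarray) -> np.ndarray:
    """Mirror a tile horizontally and vertically into a 2H×2W composite.

    Quadrants: original | horizontal mirror / vertical mirror | double
    mirror.  The composite is symmetric about both center axes, which
    removes seam artifacts when tiling.
    """
    a = np.asarray(tile)
    if a.ndim < 2 or a.size == 0:
        raise ParameterError("tile must be a non-empty 2-D array")
    top = np.concatenate([a, np.flip(a, axis=1)], axis=1)
    return np.concatenate([top, np.flip(top, axis=0)], axis=0)


def confusion_fixture(
    counts: ConfusionCounts,
    detection_thr: float,
    classification_thr: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Score/label sequences that reproduce a confusion table exactly.

    Inverse construction for :func:`trophipath.evaluation.threshold_sweep`:
    the returned (detection, classification) score pairs and boolean
    labels yield exactly the given tp/fp/tn/fn at the given thresholds.
    Both thresholds must be strictly positive whenever fn or tn is
    nonzero (a candidate can only fail a positive threshold).
    """
    if (counts.fn > 0 or counts.tn > 0) and (
        detection_thr <= 0 or classification_thr <= 0
    ):
        raise ParameterError(
            "fn/tn rows need strictly positive thresholds to fail against"
        )
    rng = np.random.default_rng(seed)

    def passing(thr: float, n: int) -> np.ndarray:
        return thr + (1.0 - thr) * rng.random(n)

    def failing(thr: float, n: int) -> np.ndarray:
        return thr * rng.random(n)

    blocks = []
    labels = []
    # true positives / false positives: pass both gates
    for n, lab in ((counts.tp, True), (counts.fp, False)):
        if n:
            blocks.append(np.column_stack(
                [passing(detection_thr, n), passing(classification_thr, n)]))
            labels.append(np.full(n, lab))
    # fn/tn: half fail detection, half fail classification
    for n, lab in ((counts.fn, True), (counts.tn, False)):
        if n:
            n_det = n // 2
            n_cls = n - n_det
            if n_det:
                blocks.append(np.column_stack(
                    [failing(detection_thr, n_det),
                     passing(classification_thr, n_det)]))
            blocks.append(np.column_stack(
                [passing(detection_thr, n_cls),
                 failing(classification_thr, n_cls)]))
            labels.append(np.full(n, lab))
    if not blocks:
        return np.empty((0, 2)), np.empty(0, dtype=bool)
    scores = np.vstack(blocks)
    labs = np.concatenate(labels)
    order = rng.permutation(len(labs))
    return scores[order], labs[order]


# ---------------------------------------------------------------------------
# packaged profiles

_DEFAULT_PROFILES = Path(__file__).parent / "data" / "profiles.yaml"

_STAT_FIELDS = (
    "entropy_dits",
    "density_pct",
    "n_small_center",
    "n_small_periphery",
    "n_large_center",
    "n_large_periphery",
    "n_mitoses",
)


def load_profiles(path: str | Path | None = None) -> dict[str, SubtypeProfile]:
    """Load subtype profiles (packaged study defaults if no path given)."""
    with open(path or _DEFAULT_PROFILES) as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, SubtypeProfile] = {}
    for name, entry in raw["subtypes"].items():
        stats = {
            f: FieldStat(mean=float(entry[f]["mean"]), sd=float(entry[f]["sd"]))
            for f in _STAT_FIELDS
        }
        out[name] = SubtypeProfile(
            subtype=name,
            pattern=entry["pattern"],
            necrosis_fraction_range=tuple(entry["necrosis_fraction_range"]),
            clustering_weight=float(entry["clustering_weight"]),
            n_cluster_sites=int(entry["n_cluster_sites"]),
            n_slides=int(entry["n_slides"]),
            **stats,
        )
    return out


__all__ = [
    "FieldStat",
    "SubtypeProfile",
    "GeneratorConfig",
    "generate_regions",
    "generate_vessels",
    "generate_mitoses",
    "generate_necrosis",
    "generate_slide",
    "generate_cohort",
    "expected_entropy",
    "calibrate_clustering_weight",
    "large_vessel_area_range_um2",
    "butterfly_reflection",
    "confusion_fixture",
    "load_profiles",
    "CLUSTER_SD_UM",
    "SMALL_VESSEL_AREA_UM2",
    "LARGE_VESSEL_AREA_MIN_UM2",
]
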