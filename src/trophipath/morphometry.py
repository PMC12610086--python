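"""Per-vessel geometry and the per-slide vessel census.

Vessel caliber is characterized independently of scanner magnification
through physical units: mask area in µm² and minimum/maximum Feret
diameters in µm.  The Feret extrema are computed on the convex hull by
the rotating-calipers construction: the maximum Feret diameter is the
hull diameter (largest distance between two vertices) and the minimum
Feret diameter is the smallest width over directions perpendicular to
hull edges, which is where the minimum of the support-width function is
attained for a convex polygon.

Vessels are split into "small" and "large" at a 300 µm² mask-area
threshold, separating capillaries from larger venules/arterioles, and
assigned to the tumor center, the peritumoral band, or neither by
centroid membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .annotations import AnnotatedSlide, RegionSet, SlideCalibration, VesselAnnotation
from .errors import ParameterError, UndefinedMetricError, ValidationError

SMALL = "small"
LARGE = "large"
CENTER = "center"
PERIPHERY = "periphery"
OUTSIDE = "outside"

#: Caliber threshold separating small from large vessels, in µm² of mask area.
DEFAULT_CALIBER_THRESHOLD_UM2 = 300.0


@dataclass(frozen=True)
class VesselMorphometry:
    """Geometry summary of a single vessel."""

    vessel_id: str
    area_um2: float
    feret_min_um: float
    feret_max_um: float
    caliber: str
    compartment: str
    invasive: bool


@dataclass(frozen=True)
class VesselCensus:
    """Per-slide compartment-by-caliber vessel counts and area density."""

    n_small_center: int
    n_small_periphery: int
    n_large_center: int
    n_large_periphery: int
    vessel_area_center_um2: float
    tumor_area_um2: float
    relative_area_density_pct: float


def polygon_area_um2(boundary: Polygon, calibration: SlideCalibration) -> float:
    """Shoelace area of a polygon in µm² (pixel area × mpp²)."""
    area_px2 = boundary.area
    if area_px2 <= 0:
        raise ValidationError("degenerate polygon: zero area")
    return area_px2 * calibration.microns_per_pixel**2


def _hull_vertices(boundary: Polygon) -> np.ndarray:
    hull = boundary.convex_hull
    if hull.geom_type != "Polygon" or hull.area <= 0:
        raise ValidationError("degenerate hull: vertices are collinear")
    # drop the repeated closing vertex
    return np.asarray(hull.exterior.coords)[:-1]


def feret_diameters(
    boundary: Polygon, calibration: SlideCalibration
) -> tuple[float, float]:
    """Minimum and maximum Feret diameters of a polygon, in µm.

    Both are properties of the convex hull.  The maximum is the hull
    diameter; the minimum is the minimum width, attained perpendicular
    to one of the hull edges, so scanning edge normals is exact.
    """
    pts = _hull_vertices(boundary)
    # max Feret: largest pairwise vertex distance (hull vertex count is
    # small for annotation polygons, O(h^2) is exact and robust)
    diffs = pts[:, None, :] - pts[None, :, :]
    feret_max = float(np.sqrt((diffs**2).sum(-1)).max())

    # min Feret: for each hull edge, the farthest vertex distance from
    # the edge's supporting line
    edges = np.roll(pts, -1, axis=0) - pts
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    good = lengths > 0
    normals = np.stack([-edges[good, 1], edges[good, 0]], axis=1) / lengths[good, None]
    # distance of every vertex from every edge line
    offsets = (pts[None, :, :] - pts[good][:, None, :]) @ normals[..., None]
    widths = np.abs(offsets[..., 0]).max(axis=1)
    feret_min = float(widths.min())
    if feret_min <= 0:
        raise ValidationError("degenerate hull: zero width")

    mpp = calibration.microns_per_pixel
    return feret_min * mpp, feret_max * mpp


def classify_caliber(
    area_um2: float, threshold_um2: float = DEFAULT_CALIBER_THRESHOLD_UM2
) -> str:
    """Small/large split at the caliber threshold.

    A vessel is ``large`` iff its area strictly exceeds the threshold;
    an area exactly at the threshold counts as small.
    """
    if threshold_um2 <= 0:
        raise ParameterError("caliber threshold must be positive")
    if area_um2 <= 0:
        raise ValidationError("vessel area must be positive")
    return LARGE if area_um2 > threshold_um2 else SMALL


def assign_compartment(vessel: VesselAnnotation, regions: RegionSet) -> str:
    """Compartment of a vessel by centroid membership.

    ``center`` if the centroid lies in a tumor polygon, ``periphery`` if
    in a peritumoral polygon, else ``outside``.  Tumor membership is
    checked first, which resolves points exactly on a shared boundary.
    """
    c = vessel.boundary.centroid
    for poly in regions.tumor:
        if poly.covers(c):
            return CENTER
    for poly in regions.peritumoral:
        if poly.covers(c):
            return PERIPHERY
    return OUTSIDE


def measure_vessels(
    slide: AnnotatedSlide,
    threshold_um2: float = DEFAULT_CALIBER_THRESHOLD_UM2,
) -> list[VesselMorphometry]:
    """Full morphometry record for every vessel on the slide."""
    out = []
    for v in slide.vessels:
        area = polygon_area_um2(v.boundary, slide.calibration)
        fmin, fmax = feret_diameters(v.boundary, slide.calibration)
        out.append(
            VesselMorphometry(
                vessel_id=v.id,
                area_um2=area,
                feret_min_um=fmin,
                feret_max_um=fmax,
                caliber=classify_caliber(area, threshold_um2),
                compartment=assign_compartment(v, slide.regions),
                invasive=v.invasive,
            )
        )
    return out


def morphometry_table(records: list[VesselMorphometry]) -> pd.DataFrame:
    """Per-slide morphometry table, one row per vessel."""
    return pd.DataFrame(
        [
            {
                "vessel_id": r.vessel_id,
                "area_um2": r.area_um2,
                "feret_min_um": r.feret_min_um,
                "feret_max_um": r.feret_max_um,
                "caliber": r.caliber,
                "compartment": r.compartment,
                "invasive": r.invasive,
            }
            for r in records
        ],
        columns=[
            "vessel_id",
            "area_um2",
            "feret_min_um",
            "feret_max_um",
            "caliber",
            "compartment",
            "invasive",
        ],
    )


def vessel_census(
    slide: AnnotatedSlide,
    threshold_um2: float = DEFAULT_CALIBER_THRESHOLD_UM2,
    records: list[VesselMorphometry] | None = None,
) -> VesselCensus:
    """Compartment-by-caliber counts plus relative area density.

    The density is the total area of vessels whose centroid lies in the
    tumor, as a percentage of the tumor area; vessels outside both
    regions are excluded from the counts.  Precomputed morphometry
    records may be passed to avoid remeasuring.
    """
    if records is None:
        records = measure_vessels(slide, threshold_um2)
    mpp2 = slide.calibration.microns_per_pixel**2
    tumor_area_um2 = slide.regions.total_tumor_area_px2() * mpp2
    if tumor_area_um2 <= 0:
        raise UndefinedMetricError("relative area density undefined: zero tumor area")

    counts = {(SMALL, CENTER): 0, (SMALL, PERIPHERY): 0,
              (LARGE, CENTER): 0, (LARGE, PERIPHERY): 0}
    center_area = 0.0
    for r in records:
        if r.compartment == CENTER:
            center_area += r.area_um2
        if r.compartment != OUTSIDE:
            counts[(r.caliber, r.compartment)] += 1

    return VesselCensus(
        n_small_center=counts[(SMALL, CENTER)],
        n_small_periphery=counts[(SMALL, PERIPHERY)],
        n_large_center=counts[(LARGE, CENTER)],
        n_large_periphery=counts[(LARGE, PERIPHERY)],
        vessel_area_center_um2=center_area,
        tumor_area_um2=tumor_area_um2,
        relative_area_density_pct=100.0 * center_area / tumor_area_um2,
    )


__all__ = [
    "VesselMorphometry",
    "VesselCensus",
    "polygon_area_um2",
    "feret_diameters",
    "classify_caliber",
    "assign_compartment",
    "measure_vessels",
    "morphometry_table",
    "vessel_census",
    "DEFAULT_CALIBER_THRESHOLD_UM2",
    "SMALL",
    "LARGE",
    "CENTER",
    "PERIPHERY",
    "OUTSIDE",
]
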