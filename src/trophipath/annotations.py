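"""Slide annotation containers, GeoJSON I/O, and tiling helpers.

A slide is represented purely by its annotation layer: a calibration
record (pixel dimensions plus microns-per-pixel), tumor and peritumoral
region polygons, vessel polygons carrying an invasion flag, mitotic-figure
points with a confidence score, and optional necrosis polygons.  Raster
pixel data is never read.

Coordinate convention: pixel units, origin at the top-left corner, y
increasing downward, 0-based.  Polygon rings are implicitly closed (the
first vertex is not repeated).  Region polygons may carry interior rings
(a peritumoral annulus has a hole where the tumor sits); vessel and
necrosis polygons are simple rings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import yaml
from shapely.geometry import Point, Polygon, box, mapping, shape

from .errors import ParameterError, ValidationError

KNOWN_CLASSES = frozenset({"tumor", "peritumoral", "vessel", "mitosis", "necrosis"})

# Fractional overlap (relative to the smaller polygon) above which tumor
# and peritumoral regions are considered to intersect rather than touch.
_OVERLAP_TOL = 1e-9


@dataclass(frozen=True)
class SlideCalibration:
    """Physical calibration of one whole-slide image."""

    slide_id: str
    width_px: int
    height_px: int
    microns_per_pixel: float

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValidationError(
                f"{self.slide_id}: slide dimensions must be >= 1 px"
            )
        if not self.microns_per_pixel > 0:
            raise ValidationError(
                f"{self.slide_id}: microns_per_pixel must be positive"
            )

    @property
    def width_um(self) -> float:
        return self.width_px * self.microns_per_pixel

    @property
    def height_um(self) -> float:
        return self.height_px * self.microns_per_pixel


@dataclass
class RegionSet:
    """Tumor and peritumoral region polygons for one slide."""

    tumor: list[Polygon]
    peritumoral: list[Polygon]

    def tumor_union(self):
        from shapely.ops import unary_union

        return unary_union(self.tumor)

    def total_tumor_area_px2(self) -> float:
        return float(sum(p.area for p in self.tumor))

    def total_peritumoral_area_px2(self) -> float:
        return float(sum(p.area for p in self.peritumoral))


@dataclass
class VesselAnnotation:
    """One vessel mask outline with its lymphovascular-invasion flag."""

    id: str
    boundary: Polygon
    invasive: bool = False


@dataclass
class MitosisAnnotation:
    """One mitotic-figure detection (point plus confidence score).

    Annotations exported without a score are treated as confirmed ground
    truth (score 1.0).
    """

    location: Point
    score: float = 1.0


@dataclass
class AnnotatedSlide:
    """The per-WSI analysis unit: calibration plus all annotations."""

    calibration: SlideCalibration
    regions: RegionSet
    vessels: list[VesselAnnotation] = field(default_factory=list)
    mitoses: list[MitosisAnnotation] = field(default_factory=list)
    necrosis: list[Polygon] = field(default_factory=list)
    subtype_label: str | None = None


@dataclass(frozen=True)
class BalanceReport:
    """Result of the 1:1 tumor/peritumoral area design check."""

    ratio: float
    tolerance: float
    passed: bool


@dataclass(frozen=True)
class Tile:
    """Axis-aligned tile rectangle in pixel coordinates, [x0,x1)x[y0,y1)."""

    x0: int
    y0: int
    x1: int
    y1: int


# ---------------------------------------------------------------------------
# validation


def _check_simple_ring(poly: Polygon, what: str, allow_holes: bool = False) -> None:
    if poly.is_empty or len(poly.exterior.coords) < 4:
        raise ValidationError(f"{what}: polygon needs at least 3 vertices")
    if not poly.is_valid:
        raise ValidationError(f"{what}: polygon is self-intersecting or invalid")
    if not allow_holes and len(poly.interiors) > 0:
        raise ValidationError(f"{what}: interior rings not allowed here")
    if poly.area <= 0:
        raise ValidationError(f"{what}: polygon has zero area")


def validate_slide(slide: AnnotatedSlide) -> None:
    """Check every structural invariant of an :class:`AnnotatedSlide`.

    Raises :class:`ValidationError` naming the offending object.
    """
    cal = slide.calibration
    bounds = box(0, 0, cal.width_px, cal.height_px)

    for kind, polys in (
        ("tumor", slide.regions.tumor),
        ("peritumoral", slide.regions.peritumoral),
    ):
        for i, poly in enumerate(polys):
            _check_simple_ring(poly, f"{kind}[{i}]", allow_holes=True)
            if not bounds.covers(poly):
                raise ValidationError(f"{kind}[{i}]: geometry out of slide bounds")
    for i, poly in enumerate(slide.necrosis):
        _check_simple_ring(poly, f"necrosis[{i}]", allow_holes=False)
        if not bounds.covers(poly):
            raise ValidationError(f"necrosis[{i}]: geometry out of slide bounds")
    for v in slide.vessels:
        _check_simple_ring(v.boundary, f"vessel {v.id}", allow_holes=False)
        if not bounds.covers(v.boundary):
            raise ValidationError(f"vessel {v.id}: geometry out of slide bounds")
    for j, m in enumerate(slide.mitoses):
        if not (0.0 <= m.score <= 1.0):
            raise ValidationError(f"mitosis[{j}]: score {m.score} outside [0,1]")
        if not bounds.covers(m.location):
            raise ValidationError(f"mitosis[{j}]: location out of slide bounds")

    # tumor and peritumoral polygons must be pairwise non-overlapping
    for i, t in enumerate(slide.regions.tumor):
        for j, p in enumerate(slide.regions.peritumoral):
            inter = t.intersection(p).area
            if inter > _OVERLAP_TOL * min(t.area, p.area):
                raise ValidationError(
                    f"tumor[{i}] overlaps peritumoral[{j}] (area {inter:.3g} px^2)"
                )


# ---------------------------------------------------------------------------
# GeoJSON I/O


def _polygon_feature(poly: Polygon, props: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(poly), "properties": props}


def write_slide(slide: AnnotatedSlide, path: str | Path) -> None:
    """Write one slide as a GeoJSON FeatureCollection.

    One feature per annotation object; the annotation class and
    per-object attributes (``invasive``, ``score``) live under feature
    properties.  Coordinates are serialized with full float precision so
    a write/read round trip is the identity.
    """
    validate_slide(slide)
    features: list[dict] = []
    for poly in slide.regions.tumor:
        features.append(_polygon_feature(poly, {"class": "tumor"}))
    for poly in slide.regions.peritumoral:
        features.append(_polygon_feature(poly, {"class": "peritumoral"}))
    for poly in slide.necrosis:
        features.append(_polygon_feature(poly, {"class": "necrosis"}))
    for v in slide.vessels:
        features.append(
            _polygon_feature(v.boundary, {"class": "vessel", "id": v.id,
                                          "invasive": bool(v.invasive)})
        )
    for m in slide.mitoses:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(m.location),
                "properties": {"class": "mitosis", "score": float(m.score)},
            }
        )
    collection = {
        "type": "FeatureCollection",
        "properties": {
            "slide_id": slide.calibration.slide_id,
            "subtype": slide.subtype_label,
        },
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(collection, fh)


def read_slide(path: str | Path, calibration: SlideCalibration) -> AnnotatedSlide:
    """Read and validate a GeoJSON FeatureCollection written by this package.

    Unknown feature classes are rejected; malformed or out-of-bounds
    geometry raises :class:`ValidationError` naming the feature.
    """
    with open(path) as fh:
        collection = json.load(fh)
    if collection.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: not a GeoJSON FeatureCollection")

    tumor: list[Polygon] = []
    peritumoral: list[Polygon] = []
    necrosis: list[Polygon] = []
    vessels: list[VesselAnnotation] = []
    mitoses: list[MitosisAnnotation] = []

    for i, feat in enumerate(collection.get("features", [])):
        props = feat.get("properties") or {}
        cls = props.get("class")
        fid = props.get("id", f"feature[{i}]")
        if cls not in KNOWN_CLASSES:
            raise ValidationError(f"{fid}: unknown annotation class {cls!r}")
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:  # malformed geometry dict
            raise ValidationError(f"{fid}: malformed geometry ({exc})") from exc
        if cls == "mitosis":
            if not isinstance(geom, Point):
                raise ValidationError(f"{fid}: mitosis feature must be a Point")
            mitoses.append(
                MitosisAnnotation(location=geom, score=float(props.get("score", 1.0)))
            )
            continue
        if not isinstance(geom, Polygon):
            raise ValidationError(f"{fid}: {cls} feature must be a Polygon")
        if cls == "tumor":
            tumor.append(geom)
        elif cls == "peritumoral":
            peritumoral.append(geom)
        elif cls == "necrosis":
            necrosis.append(geom)
        else:  # vessel
            vessels.append(
                VesselAnnotation(
                    id=str(props.get("id", f"vessel_{len(vessels)}")),
                    boundary=geom,
                    invasive=bool(props.get("invasive", False)),
                )
            )

    meta = collection.get("properties") or {}
    slide = AnnotatedSlide(
        calibration=calibration,
        regions=RegionSet(tumor=tumor, peritumoral=peritumoral),
        vessels=vessels,
        mitoses=mitoses,
        necrosis=necrosis,
        subtype_label=meta.get("subtype"),
    )
    validate_slide(slide)
    return slide


def write_calibration(calibrations: Sequence[SlideCalibration], path: str | Path) -> None:
    """Write calibration sidecar records as YAML (list of mappings)."""
    records = [
        {
            "slide_id": c.slide_id,
            "width_px": c.width_px,
            "height_px": c.height_px,
            "microns_per_pixel": c.microns_per_pixel,
        }
        for c in calibrations
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(records, fh, sort_keys=False)


def read_calibration(path: str | Path) -> dict[str, SlideCalibration]:
    """Read a YAML calibration sidecar; returns a slide_id -> record map."""
    with open(path) as fh:
        records = yaml.safe_load(fh)
    out = {}
    for r in records:
        cal = SlideCalibration(
            slide_id=str(r["slide_id"]),
            width_px=int(r["width_px"]),
            height_px=int(r["height_px"]),
            microns_per_pixel=float(r["microns_per_pixel"]),
        )
        out[cal.slide_id] = cal
    return out


# ---------------------------------------------------------------------------
# design checks and tiling


def check_region_balance(regions: RegionSet, tolerance: float = 0.05) -> BalanceReport:
    """Check the 1:1 tumor/peritumoral area design.

    ratio = total peritumoral area / total tumor area; the check passes
    iff ``|ratio - 1| <= tolerance``.  The report is advisory: real
    annotations deviate from the design and the pipeline proceeds either
    way.
    """
    if not regions.tumor or not regions.peritumoral:
        raise ValidationError("region balance needs both tumor and peritumoral polygons")
    tumor_area = regions.total_tumor_area_px2()
    if tumor_area <= 0:
        raise ValidationError("region balance undefined: zero tumor area")
    ratio = regions.total_peritumoral_area_px2() / tumor_area
    return BalanceReport(ratio=ratio, tolerance=tolerance,
                         passed=abs(ratio - 1.0) <= tolerance)


def sliding_window(
    calibration: SlideCalibration, tile_px: int, overlap_fraction: float = 0.1
) -> Iterator[Tile]:
    """Generate tile rectangles covering the slide with fixed overlap.

    The stride is ``round(tile_px * (1 - overlap_fraction))``; the last
    row and column are clamped to the slide boundary so the union of
    tiles covers every pixel.
    """
    if not (0.0 <= overlap_fraction < 1.0):
        raise ParameterError("overlap_fraction must be in [0, 1)")
    if tile_px < 1 or tile_px > min(calibration.width_px, calibration.height_px):
        raise ParameterError("tile_px must be in [1, min(width, height)]")
    stride = max(1, round(tile_px * (1.0 - overlap_fraction)))

    def starts(extent: int) -> list[int]:
        xs = list(range(0, extent - tile_px + 1, stride))
        if not xs or xs[-1] != extent - tile_px:
            xs.append(extent - tile_px)
        return xs

    for y0 in starts(calibration.height_px):
        for x0 in starts(calibration.width_px):
            yield Tile(x0=x0, y0=y0, x1=x0 + tile_px, y1=y0 + tile_px)


__all__ = [
    "SlideCalibration",
    "RegionSet",
    "VesselAnnotation",
    "MitosisAnnotation",
    "AnnotatedSlide",
    "BalanceReport",
    "Tile",
    "validate_slide",
    "read_slide",
    "write_slide",
    "read_calibration",
    "write_calibration",
    "check_region_balance",
    "sliding_window",
]
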