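"""Spatial statistics of mitotic figures.

Mitoses inside the tumor are binned onto a square grid (default cell
500 µm) over the tumor bounding box.  The headline statistic is the
Shannon entropy of the cell-occupancy distribution in base 10 — "dits"
(decimal digits of information): low entropy means mitoses concentrate
in a few clusters, high entropy means diffuse proliferation.  The
module also flags hot-spot cells and measures how strongly mitoses
gather around vessels (perivascular fraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely import STRtree

from .annotations import AnnotatedSlide
from .errors import ParameterError, ValidationError

#: Default grid cell size for mitosis binning, µm.
DEFAULT_GRID_CELL_UM = 500.0
#: Default radius for the perivascular-mitosis neighborhood, µm.
DEFAULT_PERIVASCULAR_RADIUS_UM = 100.0
#: Default nonzero-count quantile defining hot spots.
DEFAULT_HOTSPOT_QUANTILE = 0.95


@dataclass
class MitosisGrid:
    """Gridded tumor-mitosis counts over the tumor bounding box.

    ``counts[i, j]`` is the number of tumor mitoses in row i (y), column
    j (x).  ``tumor_mask`` marks cells whose center lies in the tumor;
    boundary cells that received a mitosis are also marked, so the sum
    of counts over masked cells always equals the number of tumor
    mitoses.
    """

    cell_size_um: float
    origin_um: tuple[float, float]
    counts: np.ndarray
    tumor_mask: np.ndarray

    @property
    def n_tumor_cells(self) -> int:
        return int(self.tumor_mask.sum())

    @property
    def n_mitoses(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ProliferationMetrics:
    """Per-slide proliferation summary."""

    entropy_dits: float
    n_mitoses_tumor: int
    hotspot_cells: tuple[tuple[int, int], ...]
    perivascular_fraction: float


def _tumor_mitos_xy_um(slide: AnnotatedSlide) -> np.ndarray:
    """Coordinates (µm) of mitoses lying inside the tumor region."""
    if not slide.mitoses:
        return np.empty((0, 2))
    mpp = slide.calibration.microns_per_pixel
    xy = np.array([[m.location.x, m.location.y] for m in slide.mitoses])
    inside = np.zeros(len(xy), dtype=bool)
    for poly in slide.regions.tumor:
        inside |= shapely.contains_xy(poly, xy[:, 0], xy[:, 1])
    return xy[inside] * mpp


def bin_mitoses(
    slide: AnnotatedSlide, cell_size_um: float = DEFAULT_GRID_CELL_UM
) -> MitosisGrid:
    """Assign tumor mitoses to grid cells by floor division of µm coords.

    A mitosis exactly on a cell boundary goes to the higher-index cell
    (floor rule).  Mitoses outside the tumor are excluded.  A cell
    larger than the tumor bounding box degenerates to a single-cell
    grid.
    """
    if cell_size_um <= 0:
        raise ParameterError("cell_size_um must be positive")
    if not slide.regions.tumor:
        raise ValidationError("mitosis binning needs a non-empty tumor region")

    mpp = slide.calibration.microns_per_pixel
    minx, miny, maxx, maxy = slide.regions.tumor_union().bounds
    ox, oy = minx * mpp, miny * mpp
    nx = max(1, int(np.floor((maxx * mpp - ox) / cell_size_um)) + 1)
    ny = max(1, int(np.floor((maxy * mpp - oy) / cell_size_um)) + 1)

    counts = np.zeros((ny, nx), dtype=np.int64)
    xy = _tumor_mitos_xy_um(slide)
    if len(xy):
        jj = np.floor((xy[:, 0] - ox) / cell_size_um).astype(int)
        ii = np.floor((xy[:, 1] - oy) / cell_size_um).astype(int)
        jj = np.clip(jj, 0, nx - 1)
        ii = np.clip(ii, 0, ny - 1)
        np.add.at(counts, (ii, jj), 1)

    # cell centers in pixel coords, marked if inside the tumor
    cx = (ox + (np.arange(nx) + 0.5) * cell_size_um) / mpp
    cy = (oy + (np.arange(ny) + 0.5) * cell_size_um) / mpp
    gx, gy = np.meshgrid(cx, cy)
    mask = np.zeros((ny, nx), dtype=bool)
    for poly in slide.regions.tumor:
        mask |= shapely.contains_xy(poly, gx, gy)
    mask |= counts > 0  # keep boundary cells that caught a mitosis

    return MitosisGrid(cell_size_um=cell_size_um, origin_um=(ox, oy),
                       counts=counts, tumor_mask=mask)


def mitoses_entropy(grid: MitosisGrid) -> float:
    """Shannon entropy of the mitosis cell-occupancy distribution, in dits.

    With ``p_i = count_i / N`` over occupied cells, entropy is
    ``-sum p_i log10 p_i``; an empty grid has 0 dits by convention.
    Bounded above by log10 of the number of tumor cells.
    """
    n = grid.counts.sum()
    if n == 0:
        return 0.0
    p = grid.counts[grid.counts > 0] / n
    return float(-(p * np.log10(p)).sum())


def detect_hotspots(
    grid: MitosisGrid, quantile: float = DEFAULT_HOTSPOT_QUANTILE
) -> list[tuple[int, int]]:
    """Cells whose count reaches the given quantile of nonzero counts.

    A cell must also hold at least 2 mitoses to qualify (a lone mitosis
    is never a hot spot).  Returns (row, col) indices.
    """
    if not (0.0 < quantile < 1.0):
        raise ParameterError("quantile must be in (0, 1)")
    nz = grid.counts[grid.counts > 0]
    if nz.size == 0:
        return []
    thr = max(2.0, float(np.quantile(nz, quantile)))
    ii, jj = np.nonzero(grid.counts >= thr)
    return list(zip(ii.tolist(), jj.tolist()))


def perivascular_fraction(
    slide: AnnotatedSlide, radius_um: float = DEFAULT_PERIVASCULAR_RADIUS_UM
) -> float:
    """Fraction of tumor mitoses within ``radius_um`` of a vessel boundary.

    Distance is to the nearest vessel outline; a mitosis inside a vessel
    mask is within distance of the boundary whenever the boundary is
    closer than the radius.  Returns 0 when the slide has no vessels or
    no tumor mitoses.
    """
    if radius_um <= 0:
        raise ParameterError("radius_um must be positive")
    xy_um = _tumor_mitos_xy_um(slide)
    if len(xy_um) == 0 or not slide.vessels:
        return 0.0
    mpp = slide.calibration.microns_per_pixel
    pts = shapely.points(xy_um / mpp)
    tree = STRtree([v.boundary.exterior for v in slide.vessels])
    pairs = tree.query(pts, predicate="dwithin", distance=radius_um / mpp)
    n_near = np.unique(pairs[0]).size
    return n_near / len(xy_um)


def proliferation_metrics(
    slide: AnnotatedSlide,
    cell_size_um: float = DEFAULT_GRID_CELL_UM,
    hotspot_quantile: float = DEFAULT_HOTSPOT_QUANTILE,
    perivascular_radius_um: float = DEFAULT_PERIVASCULAR_RADIUS_UM,
) -> ProliferationMetrics:
    """Convenience wrapper computing the full per-slide summary."""
    grid = bin_mitoses(slide, cell_size_um)
    return ProliferationMetrics(
        entropy_dits=mitoses_entropy(grid),
        n_mitoses_tumor=grid.n_mitoses,
        hotspot_cells=tuple(detect_hotspots(grid, hotspot_quantile)),
        perivascular_fraction=perivascular_fraction(slide, perivascular_radius_um),
    )


__all__ = [
    "MitosisGrid",
    "ProliferationMetrics",
    "bin_mitoses",
    "mitoses_entropy",
    "detect_hotspots",
    "perivascular_fraction",
    "proliferation_metrics",
    "DEFAULT_GRID_CELL_UM",
    "DEFAULT_PERIVASCULAR_RADIUS_UM",
    "DEFAULT_HOTSPOT_QUANTILE",
]
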