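"""Vessel geometry: areas, Feret diameters, caliber, compartments, census."""

import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from trophipath.annotations import (
    AnnotatedSlide,
    RegionSet,
    SlideCalibration,
    VesselAnnotation,
)
from trophipath.errors import ParameterError, UndefinedMetricError, ValidationError
from trophipath.morphometry import (
    CENTER,
    OUTSIDE,
    PERIPHERY,
    assign_compartment,
    classify_caliber,
    feret_diameters,
    measure_vessels,
    polygon_area_um2,
    vessel_census,
)

from conftest import square


def brute_force_feret(coords: np.ndarray, n_angles: int = 3600):
    """Min/max projected extent over a dense grid of directions."""
    angles = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = coords @ dirs.T  # (n_pts, n_angles)
    extents = proj.max(axis=0) - proj.min(axis=0)
    return float(extents.min()), float(extents.max())


def assert_feret_matches_brute_force(fmin, fmax, coords, n_angles=3600):
    """Exact calipers vs angle-grid scan, discretization-aware.

    The width function is an envelope of cosines: its maxima are smooth
    (grid error is second order, below 1e-6 relative at this grid), but
    its minimum sits at a kink, so the grid overshoots the true minimum
    by at most fmax*(step/2) (first order).  The calipers result must
    lie below the grid value by no more than that bound.
    """
    bmin, bmax = brute_force_feret(coords, n_angles)
    assert fmax == pytest.approx(bmax, rel=1e-6)
    step = np.pi / n_angles
    assert -1e-9 * fmax <= bmin - fmin <= fmax * step / 2 + 1e-9


def random_polygon(rng: np.random.Generator) -> Polygon:
    n = rng.integers(4, 30)
    pts = rng.uniform(0, 100, size=(n, 2))
    hull = Polygon(pts).convex_hull
    if hull.geom_type != "Polygon":
        return random_polygon(rng)
    return hull


class TestArea:
    def test_unit_square(self, unit_cal):
        assert polygon_area_um2(square(0, 0, 1), unit_cal) == pytest.approx(1.0)

    def test_scaling_with_mpp(self):
        cal = SlideCalibration("s", 100, 100, 0.5)
        assert polygon_area_um2(square(0, 0, 10), cal) == pytest.approx(25.0)

    def test_degenerate_polygon_errors(self, unit_cal):
        line = Polygon([(0, 0), (5, 5), (10, 10)])
        with pytest.raises(ValidationError):
            polygon_area_um2(line, unit_cal)

    def test_monte_carlo_oracle(self, unit_cal):
        """Shoelace area agrees with a point-in-polygon MC estimate within 1%."""
        rng = np.random.default_rng(5)
        poly = random_polygon(rng)
        minx, miny, maxx, maxy = poly.bounds
        n = 200_000
        xs = rng.uniform(minx, maxx, n)
        ys = rng.uniform(miny, maxy, n)
        import shapely

        frac = shapely.contains_xy(poly, xs, ys).mean()
        mc_area = frac * (maxx - minx) * (maxy - miny)
        assert polygon_area_um2(poly, unit_cal) == pytest.approx(mc_area, rel=0.01)


class TestFeret:
    def test_unit_square(self, unit_cal):
        fmin, fmax = feret_diameters(square(0, 0, 1), unit_cal)
        assert fmin == pytest.approx(1.0)
        assert fmax == pytest.approx(math.sqrt(2.0))

    def test_thin_rectangle(self, unit_cal):
        fmin, fmax = feret_diameters(square(0, 0, 1).union(square(0, 0, 1)), unit_cal)
        rect = Polygon([(0, 0), (100, 0), (100, 1), (0, 1)])
        fmin, fmax = feret_diameters(rect, unit_cal)
        assert fmin == pytest.approx(1.0)
        assert fmax == pytest.approx(math.hypot(100, 1))

    def test_scales_with_mpp(self):
        cal = SlideCalibration("s", 100, 100, 2.0)
        fmin, fmax = feret_diameters(square(0, 0, 10), cal)
        assert fmin == pytest.approx(20.0)
        assert fmax == pytest.approx(20.0 * math.sqrt(2))

    def test_circle_min_equals_max(self, unit_cal):
        t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        circle = Polygon(np.column_stack([10 * np.cos(t), 10 * np.sin(t)]))
        fmin, fmax = feret_diameters(circle, unit_cal)
        assert fmax == pytest.approx(20.0, rel=1e-3)
        assert fmin == pytest.approx(fmax, rel=1e-3)

    def test_rotation_translation_invariance(self, unit_cal):
        rng = np.random.default_rng(11)
        poly = random_polygon(rng)
        ref = feret_diameters(poly, unit_cal)
        coords = np.asarray(poly.exterior.coords)
        theta, dx, dy = 0.7123, 31.0, -17.5
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = Polygon(coords @ rot.T + [dx, dy])
        got = feret_diameters(moved, unit_cal)
        assert got[0] == pytest.approx(ref[0], rel=1e-9)
        assert got[1] == pytest.approx(ref[1], rel=1e-9)

    def test_collinear_vertices_error(self, unit_cal):
        with pytest.raises(ValidationError):
            feret_diameters(Polygon([(0, 0), (1, 1), (2, 2), (3, 3)]), unit_cal)

    def test_min_never_exceeds_max_and_matches_brute_force(self, unit_cal):
        rng = np.random.default_rng(7)
        for _ in range(25):
            poly = random_polygon(rng)
            fmin, fmax = feret_diameters(poly, unit_cal)
            assert 0 < fmin <= fmax
            assert_feret_matches_brute_force(
                fmin, fmax, np.asarray(poly.exterior.coords)[:-1]
            )


class TestCaliber:
    def test_threshold_tie_is_small(self):
        assert classify_caliber(300.0) == "small"
        assert classify_caliber(300.1) == "large"
        assert classify_caliber(20.0) == "small"

    def test_monotone_in_area(self):
        areas = np.linspace(1, 1000, 500)
        labels = [classify_caliber(a) for a in areas]
        first_large = labels.index("large")
        assert all(l == "small" for l in labels[:first_large])
        assert all(l == "large" for l in labels[first_large:])

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            classify_caliber(10.0, threshold_um2=0.0)
        with pytest.raises(ValidationError):
            classify_caliber(0.0)


class TestCompartment:
    def test_trivial_memberships(self, toy_slide):
        assert assign_compartment(toy_slide.vessels[0], toy_slide.regions) == CENTER
        assert assign_compartment(toy_slide.vessels[1], toy_slide.regions) == OUTSIDE
        v_peri = VesselAnnotation("p", square(420, 120, 5))
        assert assign_compartment(v_peri, toy_slide.regions) == PERIPHERY

    def test_matches_point_in_polygon_brute_force(self, toy_slide):
        """Random vessels classified identically to direct PIP on centroids."""
        import shapely

        rng = np.random.default_rng(3)
        regions = toy_slide.regions
        for _ in range(300):
            cx, cy = rng.uniform(50, 600, 2)
            v = VesselAnnotation("r", square(cx, cy, 4))
            c = v.boundary.centroid
            if regions.tumor[0].covers(c):
                expect = CENTER
            elif regions.peritumoral[0].covers(c):
                expect = PERIPHERY
            else:
                expect = OUTSIDE
            assert assign_compartment(v, regions) == expect


class TestCensus:
    def test_density_arithmetic(self, unit_cal):
        """One 5 µm² vessel in a 10,000 µm² tumor gives 0.05% density."""
        tumor = square(0, 0, 100)
        vessel = VesselAnnotation("v", Polygon([(10, 10), (15, 10), (15, 11),
                                                (10, 11)]))
        slide = AnnotatedSlide(
            calibration=unit_cal,
            regions=RegionSet(tumor=[tumor], peritumoral=[square(200, 0, 100)]),
            vessels=[vessel],
        )
        census = vessel_census(slide)
        assert census.tumor_area_um2 == pytest.approx(10_000.0)
        assert census.relative_area_density_pct == pytest.approx(0.05)
        assert census.n_small_center == 1

    def test_no_vessels(self, unit_cal):
        slide = AnnotatedSlide(
            calibration=unit_cal,
            regions=RegionSet(tumor=[square(0, 0, 100)],
                              peritumoral=[square(200, 0, 100)]),
        )
        census = vessel_census(slide)
        assert (census.n_small_center, census.n_small_periphery,
                census.n_large_center, census.n_large_periphery) == (0, 0, 0, 0)
        assert census.relative_area_density_pct == 0.0

    def test_count_conservation(self, toy_slide):
        """center + periphery counts + outside vessels = total vessels."""
        records = measure_vessels(toy_slide)
        census = vessel_census(toy_slide, records=records)
        n_outside = sum(1 for r in records if r.compartment == OUTSIDE)
        counted = (census.n_small_center + census.n_small_periphery
                   + census.n_large_center + census.n_large_periphery)
        assert counted + n_outside == len(toy_slide.vessels)

    def test_caliber_consistency(self, toy_slide):
        for r in measure_vessels(toy_slide):
            assert (r.caliber == "large") == (r.area_um2 > 300.0)
            assert 0 < r.feret_min_um <= r.feret_max_um
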