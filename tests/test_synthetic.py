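"""Synthetic-cohort generator: regions, vessels, mitoses, fixtures, determinism."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from trophipath.annotations import check_region_balance, validate_slide
from trophipath.errors import ParameterError
from trophipath.evaluation import ConfusionCounts, threshold_sweep
from trophipath.morphometry import polygon_area_um2
from trophipath.proliferation import bin_mitoses, mitoses_entropy
from trophipath.synthetic import (
    FieldStat,
    GeneratorConfig,
    butterfly_reflection,
    confusion_fixture,
    generate_cohort,
    generate_mitoses,
    generate_regions,
    generate_slide,
    generate_vessels,
    load_profiles,
)

#: scaled-down geometry for fast structural tests (not the study conditions)
SMALL = GeneratorConfig(seed=5, slide_size_um=(20_000.0, 16_000.0),
                        tumor_area_um2=9e7)


def small_profile(profiles, name, **overrides):
    p = profiles[name]
    p = replace(p, n_mitoses=FieldStat(800, 0))
    return replace(p, **overrides) if overrides else p


class TestRegions:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_area_balance_by_construction(self, seed):
        rng = np.random.default_rng(seed)
        regions = generate_regions(SMALL, rng)
        report = check_region_balance(regions, tolerance=0.05)
        assert report.passed
        # annulus ring equals tumor area exactly (same shape scaled by sqrt 2)
        assert report.ratio == pytest.approx(1.0, abs=1e-9)

    def test_tumor_area_matches_config(self):
        rng = np.random.default_rng(3)
        regions = generate_regions(SMALL, rng)
        mpp2 = 2.0**2
        assert regions.total_tumor_area_px2() * mpp2 == pytest.approx(
            SMALL.tumor_area_um2, rel=1e-9
        )

    def test_seeds_give_different_shapes(self):
        r1 = generate_regions(SMALL, np.random.default_rng(1))
        r2 = generate_regions(SMALL, np.random.default_rng(2))
        assert not r1.tumor[0].equals(r2.tumor[0])


class TestVessels:
    def test_zero_sd_counts_equal_rounded_means(self, profiles):
        p = profiles["papillary"]
        p = replace(
            p,
            n_small_center=FieldStat(13.3, 0), n_small_periphery=FieldStat(53.3, 0),
            n_large_center=FieldStat(4.84, 0), n_large_periphery=FieldStat(18.69, 0),
        )
        rng = np.random.default_rng(8)
        regions = generate_regions(SMALL, rng)
        vessels = generate_vessels(p, regions, SMALL, rng)
        assert len(vessels) == 13 + 53 + 5 + 19

    def test_small_vessels_respect_caliber_threshold(self, profiles):
        rng = np.random.default_rng(9)
        regions = generate_regions(SMALL, rng)
        cal_mpp = SMALL.microns_per_pixel
        from trophipath.annotations import SlideCalibration

        cal = SlideCalibration("s", 10_000, 8_000, cal_mpp)
        vessels = generate_vessels(profiles["acinar"], regions, SMALL, rng)
        areas = np.array([polygon_area_um2(v.boundary, cal) for v in vessels])
        # small law support is (20, 300], large law support is (300, 1.2e6]
        assert areas.min() >= 20.0 * 0.99
        assert areas.max() <= 1.2e6 * 1.01
        assert (areas <= 300.0 * 1.001).any() and (areas > 300.0).any()

    def test_count_means_recover_profile_means(self, profiles):
        """Empirical count means over repeated draws sit within 3 SE of targets."""
        p = profiles["solid"]
        rng = np.random.default_rng(10)
        regions = generate_regions(SMALL, rng)
        n_rep = 150
        counts = {"n_small_center": [], "n_large_center": []}
        for _ in range(n_rep):
            vessels = generate_vessels(p, regions, SMALL, rng)
            small = sum(
                1 for v in vessels
                if regions.tumor[0].covers(v.boundary.centroid)
                and v.boundary.area * 4 <= 300.0
            )
            large = sum(
                1 for v in vessels
                if regions.tumor[0].covers(v.boundary.centroid)
                and v.boundary.area * 4 > 300.0
            )
            counts["n_small_center"].append(small)
            counts["n_large_center"].append(large)
        for field in counts:
            target = getattr(p, field).mean
            vals = np.asarray(counts[field], float)
            se = vals.std(ddof=1) / np.sqrt(n_rep)
            assert abs(vals.mean() - target) <= 3 * se + 0.5


class TestMitoses:
    def test_uniform_limit_high_entropy(self, profiles):
        p = small_profile(profiles, "micropapillary", clustering_weight=0.0,
                          n_mitoses=FieldStat(3000, 0))
        rng = np.random.default_rng(11)
        slide = generate_slide(p, SMALL, "s", rng)
        H = mitoses_entropy(bin_mitoses(slide, 500.0))
        n_cells = bin_mitoses(slide, 500.0).n_tumor_cells
        assert H > 0.8 * np.log10(n_cells)

    def test_single_cluster_limit_low_entropy(self, profiles):
        p = small_profile(profiles, "lepidic", clustering_weight=1.0,
                          n_cluster_sites=1, n_mitoses=FieldStat(1000, 0))
        rng = np.random.default_rng(12)
        slide = generate_slide(p, SMALL, "s", rng)
        assert mitoses_entropy(bin_mitoses(slide, 500.0)) < 0.8

    def test_entropy_monotone_in_clustering_weight(self, profiles):
        means = []
        for w in (0.0, 0.5, 1.0):
            p = small_profile(profiles, "acinar", clustering_weight=w,
                              n_mitoses=FieldStat(2000, 0))
            vals = []
            for rep in range(3):
                rng = np.random.default_rng([13, rep])
                slide = generate_slide(p, SMALL, "s", rng)
                vals.append(mitoses_entropy(bin_mitoses(slide, 500.0)))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_no_vessels_falls_back_to_uniform_with_warning(self, profiles):
        p = small_profile(profiles, "acinar")
        rng = np.random.default_rng(14)
        regions = generate_regions(SMALL, rng)
        with pytest.warns(UserWarning, match="uniform"):
            mitoses = generate_mitoses(p, regions, [], SMALL, rng)
        assert len(mitoses) == 800

    def test_mitoses_inside_tumor_with_valid_scores(self, profiles):
        p = small_profile(profiles, "papillary")
        rng = np.random.default_rng(15)
        slide = generate_slide(p, SMALL, "s", rng)
        import shapely

        xy = np.array([[m.location.x, m.location.y] for m in slide.mitoses])
        assert shapely.contains_xy(slide.regions.tumor[0], xy[:, 0], xy[:, 1]).all()
        assert all(0.0 <= m.score <= 1.0 for m in slide.mitoses)


class TestCohort:
    def test_study_shaped_cohort_size(self, profiles):
        """The packaged profiles reproduce the 207-case cohort shape."""
        assert {p.subtype: p.n_slides for p in profiles.values()} == {
            "micropapillary": 15, "solid": 84, "papillary": 13,
            "lepidic": 21, "acinar": 74,
        }
        assert sum(p.n_slides for p in profiles.values()) == 207

    def test_profile_sizes_honored_and_slides_valid(self, profiles):
        subset = [
            replace(small_profile(profiles, "papillary"), n_slides=3),
            replace(small_profile(profiles, "lepidic"), n_slides=2),
        ]
        slides, manifest = generate_cohort(subset, SMALL)
        assert len(slides) == 5
        assert manifest["subtype"].tolist() == ["papillary"] * 3 + ["lepidic"] * 2
        for s in slides:
            validate_slide(s)

    def test_same_seed_byte_identical_output(self, profiles, tmp_path):
        subset = [replace(small_profile(profiles, "solid"), n_slides=2)]
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(subset, SMALL, out_dir=d1)
        generate_cohort(subset, SMALL, out_dir=d2)
        for name in ("solid_000.geojson", "solid_001.geojson",
                     "calibration.yaml", "manifest.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_requires_profiles(self):
        with pytest.raises(ParameterError):
            generate_cohort([], SMALL)


class TestButterflyReflection:
    def test_single_pixel(self):
        out = butterfly_reflection(np.array([[7.0]]))
        assert out.shape == (2, 2)
        assert (out == 7.0).all()

    def test_doubles_dimensions_and_is_mirror_symmetric(self):
        rng = np.random.default_rng(16)
        tile = rng.random((5, 8))
        out = butterfly_reflection(tile)
        assert out.shape == (10, 16)
        assert np.array_equal(out[:5, :8], tile)
        # mirror symmetry about both center axes
        assert np.array_equal(out, np.fliplr(out))
        assert np.array_equal(out, np.flipud(out))

    def test_symmetric_input_equals_tiling(self):
        tile = np.ones((3, 3)) * 4.2
        assert np.array_equal(butterfly_reflection(tile), np.tile(tile, (2, 2)))

    def test_double_application_preserves_symmetry(self):
        rng = np.random.default_rng(18)
        tile = rng.random((4, 6))
        out = butterfly_reflection(butterfly_reflection(tile))
        assert out.shape == (16, 24)
        assert np.array_equal(out, np.fliplr(out))
        assert np.array_equal(out, np.flipud(out))
        assert np.allclose(out[:8, :12], butterfly_reflection(tile))

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            butterfly_reflection(np.empty((0, 3)))


class TestConfusionFixture:
    def test_published_counts_round_trip(self):
        counts = ConfusionCounts(182, 24, 620, 26)
        scores, labels = confusion_fixture(counts, 0.3, 0.65, seed=1)
        got = threshold_sweep(scores, labels, 0.3, 0.65)
        assert (got.tp, got.fp, got.tn, got.fn) == (182, 24, 620, 26)

    def test_zero_counts_empty(self):
        scores, labels = confusion_fixture(ConfusionCounts(0, 0, 0, 0), 0.3, 0.65)
        assert len(scores) == 0 and len(labels) == 0

    def test_random_tables_exact(self):
        rng = np.random.default_rng(20)
        for i in range(100):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 300, 4))
            counts = ConfusionCounts(tp, fp, tn, fn)
            scores, labels = confusion_fixture(counts, 0.3, 0.65, seed=i)
            got = threshold_sweep(scores, labels, 0.3, 0.65)
            assert (got.tp, got.fp, got.tn, got.fn) == (tp, fp, tn, fn)

    def test_zero_threshold_with_negatives_rejected(self):
        with pytest.raises(ParameterError):
            confusion_fixture(ConfusionCounts(1, 1, 1, 1), 0.0, 0.5)
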