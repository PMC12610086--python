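"""Shared fixtures: hand-built toy slides and session-scoped synthetic cohorts."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from trophipath.annotations import (
    AnnotatedSlide,
    MitosisAnnotation,
    RegionSet,
    SlideCalibration,
    VesselAnnotation,
)
from trophipath.patterns import METRIC_FIELDS
from trophipath.pipeline import run_slide
from trophipath.synthetic import GeneratorConfig, generate_cohort, load_profiles

#: subtype -> trophic pattern correspondence used across tests
SUBTYPE_PATTERN = {
    "micropapillary": "proliferative_vascular",
    "solid": "hypoxic",
    "acinar": "proliferative",
    "papillary": "vascular",
    "lepidic": "inactive",
}


def square(x0: float, y0: float, side: float) -> Polygon:
    return Polygon([(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)])


@pytest.fixture
def unit_cal() -> SlideCalibration:
    return SlideCalibration("unit", width_px=1000, height_px=1000,
                            microns_per_pixel=1.0)


@pytest.fixture
def toy_slide(unit_cal) -> AnnotatedSlide:
    """100x100 px tumor at (100,100), equal-area peritumoral square at (400,100).

    Two vessels (one small inside the tumor, one outside both regions)
    and three mitoses (two in the tumor, one outside).
    """
    tumor = square(100, 100, 100)
    peri = square(400, 100, 100)
    vessels = [
        VesselAnnotation("v_in", square(120, 120, 5)),
        VesselAnnotation("v_out", square(700, 700, 30), invasive=True),
    ]
    mitoses = [
        MitosisAnnotation(Point(150, 150), 0.9),
        MitosisAnnotation(Point(160, 160), 0.8),
        MitosisAnnotation(Point(600, 600), 1.0),
    ]
    return AnnotatedSlide(
        calibration=unit_cal,
        regions=RegionSet(tumor=[tumor], peritumoral=[peri]),
        vessels=vessels,
        mitoses=mitoses,
    )


@pytest.fixture(scope="session")
def profiles():
    return load_profiles()


@pytest.fixture(scope="session")
def cohort50(profiles):
    """n=50 slides per subtype at seed 42, fully analyzed.

    The first 15 slides of each subtype reproduce the n=15-per-subtype
    cohort at the same seed (identical per-slide seed streams), so the
    smaller study-shaped checks reuse this cohort.
    Returns (slides, metric rows as list of dicts).
    """
    config = GeneratorConfig(seed=42, n_slides_per_subtype=50)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        slides, _ = generate_cohort(list(profiles.values()), config)
    rows = []
    for slide in slides:
        vector, _ = run_slide(slide)
        rows.append(
            {"subtype": slide.subtype_label, "slide_index_in_subtype":
             int(slide.calibration.slide_id.rsplit("_", 1)[1]),
             **{f: getattr(vector, f) for f in METRIC_FIELDS}}
        )
    return slides, rows
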