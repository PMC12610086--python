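"""Trophic-pattern classification of per-slide metric vectors.

Lung adenocarcinomas can be profiled by how they feed and grow: the
joint behavior of vascularization (vessel counts by compartment and
caliber, relative area density) and proliferation (mitoses entropy,
perivascular clustering), plus necrosis.  Five trophic patterns
summarize this behavior:

* proliferative-vascular — diffuse high mitotic activity with dual
  (central and peripheral) blood supply; typical of micropapillary.
* hypoxic — high mitotic activity, scant vasculature, large necrotic
  areas; typical of solid.
* proliferative — mitotic clustering around intratumoral vessels with
  combined central/peripheral supply; typical of acinar.
* vascular — balanced vasculature with moderate mitotic activity;
  typical of papillary.
* inactive — minimal mitotic activity, predominantly peripheral
  vessels; typical of lepidic.

The published description of these patterns is qualitative; the
quantitative decision rule here is a reconstruction: a necrosis
override (heavily necrotic, poorly vascularized slides are hypoxic)
followed by nearest-centroid assignment in z-space, where each field is
standardized by the centroid table's pooled SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError, ValidationError
from .morphometry import VesselCensus
from .proliferation import ProliferationMetrics

PATTERNS = (
    "proliferative_vascular",
    "hypoxic",
    "proliferative",
    "vascular",
    "inactive",
)

#: Necrosis fraction at or above which the hypoxic override may fire.
DEFAULT_NECROSIS_RULE_THRESHOLD = 0.10

METRIC_FIELDS = (
    "entropy_dits",
    "density_pct",
    "n_small_center",
    "n_small_periphery",
    "n_large_center",
    "n_large_periphery",
    "necrosis_fraction",
    "perivascular_fraction",
)


@dataclass(frozen=True)
class MetricVector:
    """The per-slide vascularization-proliferation profile."""

    entropy_dits: float
    density_pct: float
    n_small_center: int
    n_small_periphery: int
    n_large_center: int
    n_large_periphery: int
    necrosis_fraction: float
    perivascular_fraction: float
    slide_id: str = ""

    def __post_init__(self) -> None:
        if self.entropy_dits < 0:
            raise ValidationError("entropy_dits must be >= 0")
        if not (0.0 <= self.necrosis_fraction <= 1.0):
            raise ValidationError("necrosis_fraction must be in [0,1]")
        if not (0.0 <= self.perivascular_fraction <= 1.0):
            raise ValidationError("perivascular_fraction must be in [0,1]")
        if not (0.0 <= self.density_pct <= 100.0):
            raise ValidationError("density_pct must be in [0,100]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in METRIC_FIELDS], dtype=float)


@dataclass(frozen=True)
class PatternCentroid:
    """Mean/SD of every metric field for one trophic pattern."""

    pattern: str
    subtype: str
    means: dict[str, float]
    sds: dict[str, float]

    def mean_array(self) -> np.ndarray:
        return np.array([self.means[f] for f in METRIC_FIELDS], dtype=float)

    def sd_array(self) -> np.ndarray:
        return np.array([self.sds[f] for f in METRIC_FIELDS], dtype=float)


def assemble_metric_vector(
    census: VesselCensus,
    prolif: ProliferationMetrics,
    necrosis_fraction: float,
    slide_id: str = "",
) -> MetricVector:
    """Join the vessel census and proliferation summary into one vector."""
    return MetricVector(
        entropy_dits=prolif.entropy_dits,
        density_pct=census.relative_area_density_pct,
        n_small_center=census.n_small_center,
        n_small_periphery=census.n_small_periphery,
        n_large_center=census.n_large_center,
        n_large_periphery=census.n_large_periphery,
        necrosis_fraction=necrosis_fraction,
        perivascular_fraction=prolif.perivascular_fraction,
        slide_id=slide_id,
    )


def pooled_sds(centroids: Sequence[PatternCentroid]) -> np.ndarray:
    """Per-field pooled SD: root-mean-square of the centroid SDs."""
    sds = np.stack([c.sd_array() for c in centroids])
    pooled = np.sqrt((sds**2).mean(axis=0))
    if np.any(pooled <= 0):
        bad = [f for f, s in zip(METRIC_FIELDS, pooled) if s <= 0]
        raise ValidationError(f"degenerate pooled SDs for fields: {bad}")
    return pooled


def classify_pattern(
    v: MetricVector,
    centroids: Sequence[PatternCentroid],
    necrosis_rule_threshold: float = DEFAULT_NECROSIS_RULE_THRESHOLD,
) -> tuple[str, dict[str, float]]:
    """Assign a trophic pattern to one metric vector.

    Stage 1 (rule): a slide with necrosis fraction at or above the
    threshold AND relative density below the hypoxic centroid's density
    mean is hypoxic outright — necrosis with failing vasculature defines
    that pattern.  Stage 2: nearest centroid by Euclidean distance in
    z-space (fields standardized by the table's pooled SDs), ties broken
    by centroid order.  Returns the pattern and the per-pattern distance
    scores (smaller is closer).
    """
    if len(centroids) < 2:
        raise ParameterError("need at least two centroids")
    pooled = pooled_sds(centroids)
    x = v.as_array() / pooled
    scores: dict[str, float] = {}
    best, best_d = None, math.inf
    for c in centroids:
        d = float(np.linalg.norm(x - c.mean_array() / pooled))
        scores[c.pattern] = d
        if d < best_d:
            best, best_d = c.pattern, d

    hypoxic = next((c for c in centroids if c.pattern == "hypoxic"), None)
    if (
        hypoxic is not None
        and v.necrosis_fraction >= necrosis_rule_threshold
        and v.density_pct < hypoxic.means["density_pct"]
    ):
        return "hypoxic", scores
    return best, scores


def cohort_summary(
    vectors: Sequence[MetricVector], labels: Sequence[str]
) -> pd.DataFrame:
    """Per-group mean ± SD table over all metric fields.

    SD uses the n-1 denominator; groups of size 1 report NaN SD
    (undefined).  Rows are groups; columns are a (field, statistic)
    MultiIndex plus an ``n`` column.
    """
    if len(vectors) != len(labels):
        raise ValidationError("vectors and labels length mismatch")
    df = metric_table(vectors)
    df["group"] = list(labels)
    agg = df.groupby("group")[list(METRIC_FIELDS)].agg(["mean", "std"])
    agg["n"] = df.groupby("group").size()
    return agg


def metric_table(vectors: Sequence[MetricVector]) -> pd.DataFrame:
    """One row per slide with all metric fields."""
    return pd.DataFrame(
        [
            {"slide_id": v.slide_id, **{f: getattr(v, f) for f in METRIC_FIELDS}}
            for v in vectors
        ],
        columns=["slide_id", *METRIC_FIELDS],
    )


# ---------------------------------------------------------------------------
# centroid table I/O

_DEFAULT_CENTROIDS = Path(__file__).parent / "data" / "centroids.yaml"


def load_centroids(path: str | Path | None = None) -> list[PatternCentroid]:
    """Load the pattern centroid table (packaged defaults if no path)."""
    with open(path or _DEFAULT_CENTROIDS) as fh:
        raw = yaml.safe_load(fh)
    out = []
    for entry in raw["centroids"]:
        means = {f: float(entry["means"][f]) for f in METRIC_FIELDS}
        sds = {f: float(entry["sds"][f]) for f in METRIC_FIELDS}
        out.append(
            PatternCentroid(pattern=entry["pattern"], subtype=entry.get("subtype", ""),
                            means=means, sds=sds)
        )
    return out


__all__ = [
    "PATTERNS",
    "METRIC_FIELDS",
    "MetricVector",
    "PatternCentroid",
    "assemble_metric_vector",
    "classify_pattern",
    "cohort_summary",
    "metric_table",
    "pooled_sds",
    "load_centroids",
    "DEFAULT_NECROSIS_RULE_THRESHOLD",
]
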