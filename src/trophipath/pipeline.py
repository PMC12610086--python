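"""Per-slide and cohort orchestration.

``run_slide`` turns one annotated slide into its morphometry table,
metric row, and (optionally) heatmap PNGs; ``run_cohort`` maps that over
a manifest and adds the per-subtype summary plus trophic-pattern calls.
All outputs are deterministic for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import heatmaps as hm
from .annotations import AnnotatedSlide, read_calibration, read_slide
from .errors import TrophipathError, ValidationError
from .morphometry import (
    DEFAULT_CALIBER_THRESHOLD_UM2,
    measure_vessels,
    morphometry_table,
    vessel_census,
)
from .patterns import (
    DEFAULT_NECROSIS_RULE_THRESHOLD,
    MetricVector,
    assemble_metric_vector,
    classify_pattern,
    cohort_summary,
    load_centroids,
    metric_table,
)
from .proliferation import (
    DEFAULT_GRID_CELL_UM,
    DEFAULT_HOTSPOT_QUANTILE,
    DEFAULT_PERIVASCULAR_RADIUS_UM,
    proliferation_metrics,
)

logger = logging.getLogger("trophipath")


@dataclass
class PipelineConfig:
    """All analysis parameters; round-trips through YAML unchanged."""

    caliber_threshold_um2: float = DEFAULT_CALIBER_THRESHOLD_UM2
    grid_cell_um: float = DEFAULT_GRID_CELL_UM
    hotspot_quantile: float = DEFAULT_HOTSPOT_QUANTILE
    perivascular_radius_um: float = DEFAULT_PERIVASCULAR_RADIUS_UM
    heatmap_bandwidth_um: float = hm.DEFAULT_BANDWIDTH_UM
    heatmap_cell_um: float = hm.DEFAULT_HEATMAP_CELL_UM
    segmented_break_quantiles: tuple[float, ...] = hm.DEFAULT_BREAK_QUANTILES
    necrosis_rule_threshold: float = DEFAULT_NECROSIS_RULE_THRESHOLD
    centroids_path: str | None = None
    seed: int = 0
    output_dir: str = "trophipath_out"

    def __post_init__(self) -> None:
        for name in ("caliber_threshold_um2", "grid_cell_um",
                     "perivascular_radius_um", "heatmap_bandwidth_um",
                     "heatmap_cell_um"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["segmented_break_quantiles"] = list(self.segmented_break_quantiles)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "segmented_break_quantiles" in data:
            data["segmented_break_quantiles"] = tuple(
                data["segmented_break_quantiles"]
            )
        return cls(**data)


def necrosis_fraction(slide: AnnotatedSlide) -> float:
    """Necrosis area as a fraction of tumor area (0 without necrosis)."""
    tumor = slide.regions.total_tumor_area_px2()
    if tumor <= 0:
        return 0.0
    return float(sum(p.area for p in slide.necrosis)) / tumor


def run_slide(
    slide: AnnotatedSlide,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    render: bool = False,
) -> tuple[MetricVector, pd.DataFrame]:
    """Analyze one slide: metric vector plus the per-vessel table.

    With ``out_dir`` set, writes the morphometry CSV (and heatmap PNGs
    when ``render`` is true).  Every parameter used is logged.
    """
    config = config or PipelineConfig()
    sid = slide.calibration.slide_id
    logger.info(
        "run_slide %s: caliber_threshold=%g um2 grid_cell=%g um "
        "perivascular_radius=%g um",
        sid, config.caliber_threshold_um2, config.grid_cell_um,
        config.perivascular_radius_um,
    )
    records = measure_vessels(slide, config.caliber_threshold_um2)
    census = vessel_census(slide, config.caliber_threshold_um2, records=records)
    prolif = proliferation_metrics(
        slide,
        cell_size_um=config.grid_cell_um,
        hotspot_quantile=config.hotspot_quantile,
        perivascular_radius_um=config.perivascular_radius_um,
    )
    vector = assemble_metric_vector(
        census, prolif, necrosis_fraction(slide), slide_id=sid
    )
    table = morphometry_table(records)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / f"{sid}_vessels.csv", index=False)
        if render:
            _render_slide_heatmaps(slide, config, out_dir)
    return vector, table


def _render_slide_heatmaps(
    slide: AnnotatedSlide, config: PipelineConfig, out_dir: Path
) -> None:
    mpp = slide.calibration.microns_per_pixel
    extent = (0.0, 0.0, slide.calibration.width_um, slide.calibration.height_um)
    mit_xy = np.array(
        [[m.location.x * mpp, m.location.y * mpp] for m in slide.mitoses]
    ).reshape(-1, 2)
    grad = hm.gradient_heatmap(
        mit_xy, extent, config.heatmap_bandwidth_um, config.heatmap_cell_um,
        channel="mitoses",
    )
    hm.render_overlay(slide, grad,
                      out_dir / f"{slide.calibration.slide_id}_mitoses.png")

    counts = grad.values * config.heatmap_cell_um**2
    nz = counts[counts > 0]
    if nz.size:
        qs = np.quantile(nz, config.segmented_break_quantiles)
        breaks = np.unique(qs[qs > 0])
        if breaks.size:
            seg = hm.segmented_heatmap(counts, breaks, config.heatmap_cell_um,
                                       channel="mitoses")
            hm.render_overlay(
                slide, seg,
                out_dir / f"{slide.calibration.slide_id}_mitoses_segmented.png",
            )


def run_cohort(
    manifest: pd.DataFrame,
    slide_dir: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Analyze every slide in a manifest and summarize per subtype.

    ``manifest`` needs columns slide_id and subtype; slides are read
    from ``slide_dir`` (GeoJSON plus calibration.yaml).  Failing slides
    are collected under ``failures`` while the rest are processed.
    Returns a dict with the cohort table, summary table, pattern calls,
    and failures.
    """
    config = config or PipelineConfig()
    slide_dir = Path(slide_dir)
    calibrations = read_calibration(slide_dir / "calibration.yaml")
    centroids = load_centroids(config.centroids_path)

    vectors: list[MetricVector] = []
    labels: list[str] = []
    failures: list[dict] = []
    calls = []
    for row in manifest.itertuples():
        sid = str(row.slide_id)
        try:
            slide = read_slide(slide_dir / f"{sid}.geojson", calibrations[sid])
            vector, _ = run_slide(slide, config)
        except (TrophipathError, KeyError, OSError) as exc:
            logger.error("slide %s failed: %s", sid, exc)
            failures.append({"slide_id": sid, "error": str(exc)})
            continue
        pattern, scores = classify_pattern(
            vector, centroids, config.necrosis_rule_threshold
        )
        vectors.append(vector)
        labels.append(str(row.subtype))
        calls.append({"slide_id": sid, "subtype": str(row.subtype),
                      "pattern": pattern,
                      **{f"score_{k}": v for k, v in scores.items()}})

    cohort = metric_table(vectors)
    cohort.insert(1, "subtype", labels)
    patterns_df = pd.DataFrame(calls)
    if not patterns_df.empty:
        cohort = cohort.merge(patterns_df[["slide_id", "pattern"]], on="slide_id")
    summary = cohort_summary(vectors, labels) if vectors else pd.DataFrame()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out_dir / "cohort.csv", index=False)
        summary.to_csv(out_dir / "summary.csv")
        patterns_df.to_csv(out_dir / "patterns.csv", index=False)
        if failures:
            pd.DataFrame(failures).to_csv(out_dir / "failures.csv", index=False)
        config.to_yaml(out_dir / "effective_config.yaml")

    return {"cohort": cohort, "summary": summary, "patterns": patterns_df,
            "failures": failures}


__all__ = ["PipelineConfig", "run_slide", "run_cohort", "necrosis_fraction"]
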