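"""End-to-end orchestration: one call from cloud(s) to report tables.

``process_date`` runs the single-date chain (DTM, height normalization,
crown delineation, crown metrics, panel calibration, flower classification,
per-tree densities). ``run_time_series`` repeats it per date, matches crowns
across dates by nearest centroid and assembles the blooming calendar and
variety rankings. Both are deterministic for fixed inputs and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
from shapely.geometry.base import BaseGeometry

from .cloud import ColoredPointCloud
from .flowering import (FlowerThresholdClassifier, compute_brightness,
                        flower_density_per_tree)
from .metrics import DEFAULT_SLICE_THICKNESS, metrics_table
from .segmentation import CrownSegmenter
from .stats import build_calendar, match_trees_across_dates, rank_varieties
from .terrain import TerrainModel


@dataclass
class PipelineParams:
    """Tunable parameters of the per-date processing chain."""

    dtm_cell: float = 2.0
    dtm_quantile: float = 0.05
    min_canopy_height: float = 0.5
    chm_cell: float = 0.25
    smooth_sigma: float = 1.0
    min_peak_separation: float = 3.0
    min_crown_area: float = 0.5
    slice_thickness: float = DEFAULT_SLICE_THICKNESS
    panel: str = "grey"
    flower_min_height: float = 1.0
    row_azimuth: float = 0.0


@dataclass
class DateResult:
    """All per-date artifacts of the processing chain."""

    date: object
    cloud: ColoredPointCloud       # with brightness and normalized heights
    terrain: TerrainModel
    segmenter: CrownSegmenter
    metrics: pd.DataFrame
    panels: dict
    flower_table: pd.DataFrame
    flower_mask: object


def process_date(cloud: ColoredPointCloud,
                 panel_footprints: Mapping[str, BaseGeometry],
                 params: Optional[PipelineParams] = None, date=None,
                 panel_reflectances: Optional[Mapping[str, float]] = None,
                 ) -> DateResult:
    """Run the full single-date chain on one colored cloud."""
    params = params or PipelineParams()
    terrain = TerrainModel(cell_size=params.dtm_cell,
                           quantile=params.dtm_quantile)
    normalized = terrain.fit_transform(cloud)
    normalized = compute_brightness(normalized)

    segmenter = CrownSegmenter(
        chm_cell=params.chm_cell, smooth_sigma=params.smooth_sigma,
        min_peak_separation=params.min_peak_separation,
        min_crown_area=params.min_crown_area,
        min_canopy_height=params.min_canopy_height)
    segmenter.fit(normalized)
    canopy = normalized.subset(
        normalized.height_above_ground > params.min_canopy_height)
    # canopy subset order matches the one used inside the segmenter
    table = metrics_table(segmenter.crowns_, canopy, date=date,
                          slice_thickness=params.slice_thickness,
                          row_azimuth=params.row_azimuth)

    classifier = FlowerThresholdClassifier(panel=params.panel,
                                           min_height=params.flower_min_height)
    classifier.fit(normalized, panel_footprints,
                   reflectances=panel_reflectances)
    mask = classifier.predict(normalized)
    flowers = flower_density_per_tree(normalized, mask, segmenter.crowns_,
                                      table, classifier.reference_, date=date)
    return DateResult(date=date, cloud=normalized, terrain=terrain,
                      segmenter=segmenter, metrics=table,
                      panels=classifier.panels_, flower_table=flowers,
                      flower_mask=mask)


@dataclass
class TimeSeriesResult:
    dates: list
    per_date: list[DateResult]
    metrics: pd.DataFrame          # stacked, with global tree ids
    flower_tables: pd.DataFrame    # stacked, with global tree ids
    calendar: object = None
    rankings: dict = field(default_factory=dict)


def run_time_series(clouds_by_date: Sequence[tuple[object, ColoredPointCloud]],
                    panel_footprints: Mapping[str, BaseGeometry],
                    params: Optional[PipelineParams] = None,
                    variety_map: Optional[pd.DataFrame] = None,
                    alpha: float = 0.05) -> TimeSeriesResult:
    """Process several dates and assemble cross-date phenotyping reports.

    ``variety_map`` (tree_id, variety[, block]) refers to the global tree
    ids fixed by the first date's delineation.
    """
    params = params or PipelineParams()
    per_date = [process_date(cloud, panel_footprints, params, date=date)
                for date, cloud in clouds_by_date]
    centroid_frames = [r.metrics[["tree_id", "x", "y"]] for r in per_date]
    if len(per_date) > 1:
        mappings = match_trees_across_dates(centroid_frames)
    else:
        mappings = [{int(t): int(t) for t in centroid_frames[0]["tree_id"]}]
    metrics_frames = []
    flower_frames = []
    for result, mapping in zip(per_date, mappings):
        m = result.metrics.copy()
        m["tree_id"] = m["tree_id"].map(mapping)
        metrics_frames.append(m)
        f = result.flower_table.copy()
        f["tree_id"] = f["tree_id"].map(lambda t: mapping.get(t, -1))
        flower_frames.append(f)
    metrics = pd.concat(metrics_frames, ignore_index=True)
    flowers = pd.concat(flower_frames, ignore_index=True)
    if variety_map is not None:
        metrics = metrics.drop(columns=["variety", "block"], errors="ignore")
        metrics = metrics.merge(variety_map, on="tree_id", how="left")
        flowers = flowers.merge(variety_map[["tree_id", "variety"]],
                                on="tree_id", how="left")

    out = TimeSeriesResult(dates=[d for d, _ in clouds_by_date],
                           per_date=per_date, metrics=metrics,
                           flower_tables=flowers)
    if variety_map is not None:
        if len(per_date) > 1:
            out.calendar = build_calendar(flowers)
        first = metrics[metrics["date"] == out.dates[0]]
        for metric in ("height", "volume"):
            try:
                out.rankings[metric] = rank_varieties(first, metric,
                                                      alpha=alpha)
            except ValueError:
                pass
    return out
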