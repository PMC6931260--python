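"""Per-tree crown geometry: height, projected area, slicing volume, axes.

Crown volume follows the point-cloud slicing scheme: the crown is cut into
horizontal slabs spanning the crown's own height range (so the trunk gap
below the lowest crown point is excluded) and each slab contributes the area
of the 2D convex hull of its points times the slab thickness. Unlike a
surface-model prism sum, the slice stack follows the vertical concavity of
the crown. The slab-hull estimator has a first-order geometric bias in the
slab thickness; the 0.05 m default keeps it within a few percent on
ellipsoidal crowns (see the methods note for the convergence analysis).

Length and width are the extents of the projected points along their
principal axes, so they are invariant to horizontal rotation of the crown.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .cloud import ColoredPointCloud
from .segmentation import CrownMap

DEFAULT_SLICE_THICKNESS = 0.05


@dataclass
class TreeRecord:
    """Geometric description of one delineated crown."""

    tree_id: int
    centroid: tuple[float, float]
    max_height: float
    projected_area: float
    crown_volume: float
    length: float
    width: float
    n_points: int
    degenerate: bool = False
    variety: Optional[str] = None
    block: Optional[str] = None
    date: Optional[object] = None

    def as_dict(self) -> dict:
        return {
            "tree_id": self.tree_id, "variety": self.variety,
            "block": self.block, "date": self.date,
            "x": self.centroid[0], "y": self.centroid[1],
            "max_height_m": self.max_height,
            "projected_area_m2": self.projected_area,
            "crown_volume_m3": self.crown_volume,
            "length_m": self.length, "width_m": self.width,
            "n_points": self.n_points, "degenerate": self.degenerate,
        }


def _hull_area_2d(xy: np.ndarray) -> float:
    """Area of the 2D convex hull; 0 for < 3 points or collinear points."""
    if xy.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(xy).volume)  # qhull: 'volume' is area in 2D
    except QhullError:
        return 0.0


def slicing_volume(xy: np.ndarray, h: np.ndarray,
                   slice_thickness: float = DEFAULT_SLICE_THICKNESS) -> float:
    """Crown volume as the sum of per-slab hull areas times thickness.

    Slabs are anchored at the lowest crown point; the final slab takes the
    residual thickness so the stack spans exactly the crown height range.
    """
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be positive")
    hmin = float(h.min())
    hmax = float(h.max())
    span = hmax - hmin
    if span <= 0:
        return 0.0
    n_slabs = max(int(math.ceil(span / slice_thickness)), 1)
    edges = hmin + slice_thickness * np.arange(n_slabs + 1)
    edges[-1] = hmax
    idx = np.clip(((h - hmin) / slice_thickness).astype(int), 0, n_slabs - 1)
    volume = 0.0
    for k in range(n_slabs):
        sel = idx == k
        thickness = edges[k + 1] - edges[k]
        if thickness <= 0 or sel.sum() < 3:
            continue
        volume += _hull_area_2d(xy[sel]) * thickness
    return volume


def principal_extents(xy: np.ndarray, row_azimuth: float = 0.0,
                      ) -> tuple[float, float]:
    """(length, width) along the principal axes of the projected points.

    Length is the larger extent; on a near-tie the axis closer to the row
    azimuth (radians from +x) is reported as length.
    """
    centered = xy - xy.mean(axis=0)
    cov = np.cov(centered.T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    # eigh returns ascending eigenvalues: column 1 is the major axis
    proj = centered @ eigvecs
    extents = proj.max(axis=0) - proj.min(axis=0)
    ext_minor, ext_major = float(extents[0]), float(extents[1])
    if abs(ext_major - ext_minor) < 1e-9:
        row_dir = np.array([np.cos(row_azimuth), np.sin(row_azimuth)])
        align = np.abs(eigvecs.T @ row_dir)
        if align[0] > align[1]:
            ext_minor, ext_major = ext_major, ext_minor
    length = max(ext_major, ext_minor)
    width = min(ext_major, ext_minor)
    return length, width


def compute_metrics(crown: ColoredPointCloud,
                    slice_thickness: float = DEFAULT_SLICE_THICKNESS,
                    tree_id: int = 0, row_azimuth: float = 0.0,
                    variety: Optional[str] = None, block: Optional[str] = None,
                    date=None) -> TreeRecord:
    """Compute the five crown metrics for one crown's points.

    Crowns with fewer than four points, or whose points are (near-)
    degenerate in plan view, yield a zeroed record with the degenerate flag.
    """
    if crown.height_above_ground is None:
        raise ValueError("crown points lack heights above ground")
    xy = crown.xy
    h = crown.height_above_ground
    n = len(crown)
    centroid = (float(crown.x.mean()), float(crown.y.mean()))
    degenerate = n < 4 or _hull_area_2d(xy) == 0.0
    if degenerate:
        return TreeRecord(tree_id=tree_id, centroid=centroid, max_height=0.0,
                          projected_area=0.0, crown_volume=0.0, length=0.0,
                          width=0.0, n_points=n, degenerate=True,
                          variety=variety, block=block, date=date)
    length, width = principal_extents(xy, row_azimuth)
    return TreeRecord(
        tree_id=tree_id, centroid=centroid,
        max_height=float(h.max()),
        projected_area=_hull_area_2d(xy),
        crown_volume=slicing_volume(xy, h, slice_thickness),
        length=length, width=width, n_points=n, degenerate=False,
        variety=variety, block=block, date=date,
    )


def metrics_table(crowns: CrownMap, canopy: ColoredPointCloud,
                  date=None, slice_thickness: float = DEFAULT_SLICE_THICKNESS,
                  variety_map: Optional[pd.DataFrame] = None,
                  row_azimuth: float = 0.0) -> pd.DataFrame:
    """One metrics row per delineated crown (CSV-ready).

    ``variety_map``, when given, is a frame with tree_id/variety[/block]
    columns joined onto the output.
    """
    records = []
    for crown in crowns.crowns:
        pts = canopy.subset(crown.point_indices)
        rec = compute_metrics(pts, slice_thickness=slice_thickness,
                              tree_id=crown.crown_id, row_azimuth=row_azimuth,
                              date=date)
        rec.centroid = crown.centroid
        records.append(rec.as_dict())
    table = pd.DataFrame(records)
    if variety_map is not None:
        cols = [c for c in ("tree_id", "variety", "block") if c in variety_map]
        table = table.drop(columns=[c for c in ("variety", "block")
                                    if c in cols]).merge(
            variety_map[cols], on="tree_id", how="left")
    return table
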