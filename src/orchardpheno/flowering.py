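"""Flower-point detection by reference-panel brightness calibration.

Per-point brightness is (R + G + B) / 3 on the [0, 255] channel scale. The
observed mean brightness of a ground reference panel of known reflectance
(grey by default; white available for comparison) serves as a per-date
classification threshold, which makes the detection invariant to uniform
illumination changes between flight dates: points at least as bright as the
panel and more than 1 m above the terrain are flower points. Flower density
for a tree is the number of flower points inside its crown footprint divided
by its crown volume (flowers per m^3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from sklearn.base import BaseEstimator

from .cloud import ColoredPointCloud, LABEL_FLOWER
from .metrics import TreeRecord
from .segmentation import CrownMap

PANEL_MAX_HEIGHT = 0.3  # panels lie on the ground
RESIDUAL_TREE_ID = -1   # bucket for flower points outside every crown


@dataclass
class PanelReference:
    """Observed brightness of one reference panel."""

    panel_id: str
    footprint: BaseGeometry
    reflectance: Optional[float]
    mean_brightness: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_brightness <= 255.0:
            raise ValueError("panel mean brightness outside [0, 255]")


@dataclass
class FlowerEstimate:
    """Per-tree, per-date flower count and density."""

    tree_id: int
    date: object
    n_flower_points: int
    crown_volume: float
    flower_density: float  # NaN when volume is 0 (undefined)
    threshold_used: float
    panel_used: str

    def as_dict(self) -> dict:
        return {
            "tree_id": self.tree_id, "date": self.date,
            "n_flower_points": self.n_flower_points,
            "crown_volume_m3": self.crown_volume,
            "flower_density_per_m3": self.flower_density,
            "threshold": self.threshold_used, "panel_used": self.panel_used,
        }


def compute_brightness(cloud: ColoredPointCloud) -> ColoredPointCloud:
    """Attach per-point brightness = (r + g + b) / 3, unrounded."""
    out = cloud.copy()
    out.brightness = (out.r + out.g + out.b) / 3.0
    return out


def panel_mean_brightness(cloud: ColoredPointCloud, footprint: BaseGeometry,
                          panel_id: str, reflectance: Optional[float] = None,
                          min_points: int = 10,
                          max_height: float = PANEL_MAX_HEIGHT,
                          ) -> PanelReference:
    """Mean brightness over the points on a panel footprint.

    Only near-ground points count (height above ground below ``max_height``
    when heights are available), since the panels rest on the soil.
    """
    if cloud.brightness is None:
        raise ValueError("brightness missing; call compute_brightness first")
    inside = shapely.intersects_xy(footprint, cloud.x, cloud.y)
    if cloud.height_above_ground is not None:
        inside &= cloud.height_above_ground < max_height
    n = int(inside.sum())
    if n < min_points:
        raise ValueError(
            f"reference panel {panel_id!r}: only {n} points on its footprint "
            f"(need {min_points}); check the footprint coordinates"
        )
    return PanelReference(panel_id=panel_id, footprint=footprint,
                          reflectance=reflectance,
                          mean_brightness=float(cloud.brightness[inside].mean()),
                          n_points=n)


def classify_flower_points(cloud: ColoredPointCloud, threshold: float,
                           min_height: float = 1.0,
                           ) -> tuple[np.ndarray, ColoredPointCloud]:
    """Mark flower points: brightness >= threshold and height > min_height.

    The brightness comparison is inclusive and the height comparison strict.
    Returns the boolean flower mask and a copy of the cloud with the flower
    class label set on those points. An empty result is valid (post-bloom
    dates have no flowers).
    """
    if cloud.brightness is None:
        raise ValueError("brightness missing; call compute_brightness first")
    if cloud.height_above_ground is None:
        raise ValueError("heights above ground missing; run the DTM first")
    mask = (cloud.brightness >= threshold) & (cloud.height_above_ground > min_height)
    out = cloud.copy()
    if out.class_label is None:
        out.class_label = np.full(len(out), 0, dtype=np.uint8)
    out.class_label = out.class_label.copy()
    out.class_label[mask] = LABEL_FLOWER
    return mask, out


def flower_density_per_tree(cloud: ColoredPointCloud, flower_mask: np.ndarray,
                            crowns: CrownMap,
                            metrics: Sequence[TreeRecord] | pd.DataFrame,
                            panel: PanelReference, date=None,
                            ) -> pd.DataFrame:
    """Per-tree flower counts and densities (flowers per m^3 of crown).

    Counting is planimetric: a flower point belongs to the crown whose
    footprint polygon contains its (x, y). Flower points outside every crown
    are reported in a residual row (tree_id -1). Trees with zero crown
    volume keep their count but get an undefined (NaN) density.
    """
    if isinstance(metrics, pd.DataFrame):
        volumes = dict(zip(metrics["tree_id"], metrics["crown_volume_m3"]))
    else:
        volumes = {m.tree_id: m.crown_volume for m in metrics}
    fx = cloud.x[flower_mask]
    fy = cloud.y[flower_mask]
    assigned = np.zeros(fx.size, dtype=bool)
    rows = []
    for crown in crowns.crowns:
        inside = shapely.intersects_xy(crown.polygon, fx, fy) & ~assigned
        assigned |= inside
        count = int(inside.sum())
        volume = float(volumes.get(crown.crown_id, np.nan))
        if volume > 0:
            density = count / volume
        else:
            density = float("nan")
        rows.append(FlowerEstimate(
            tree_id=crown.crown_id, date=date, n_flower_points=count,
            crown_volume=volume, flower_density=density,
            threshold_used=panel.mean_brightness,
            panel_used=panel.panel_id).as_dict())
    residual = int((~assigned).sum())
    rows.append(FlowerEstimate(
        tree_id=RESIDUAL_TREE_ID, date=date, n_flower_points=residual,
        crown_volume=float("nan"), flower_density=float("nan"),
        threshold_used=panel.mean_brightness,
        panel_used=panel.panel_id).as_dict())
    return pd.DataFrame(rows)


class FlowerThresholdClassifier(BaseEstimator):
    """Panel-calibrated flower-point classifier (fit/predict interface).

    ``fit`` takes the scene cloud plus the panel footprints and stores the
    classification threshold (the chosen panel's observed mean brightness);
    ``predict`` returns the boolean flower mask for a cloud with brightness
    and normalized heights.

    Parameters
    ----------
    panel : {"grey", "white"}
        Which reference panel supplies the threshold. Grey is the default:
        the white panel's brightness is so high that almost no points
        qualify as flowers.
    min_height : float
        Height floor (m, strict) separating flowers from bright ground
        objects — including the panels themselves.
    """

    def __init__(self, panel: str = "grey", min_height: float = 1.0,
                 min_panel_points: int = 10):
        self.panel = panel
        self.min_height = min_height
        self.min_panel_points = min_panel_points

    def fit(self, cloud: ColoredPointCloud,
            panel_footprints: Mapping[str, BaseGeometry],
            reflectances: Optional[Mapping[str, float]] = None,
            ) -> "FlowerThresholdClassifier":
        if self.panel not in panel_footprints:
            raise ValueError(f"panel {self.panel!r} not among the footprints")
        if cloud.brightness is None:
            cloud = compute_brightness(cloud)
        self.panels_ = {}
        for pid, footprint in panel_footprints.items():
            refl = None if reflectances is None else reflectances.get(pid)
            self.panels_[pid] = panel_mean_brightness(
                cloud, footprint, pid, reflectance=refl,
                min_points=self.min_panel_points)
        self.reference_ = self.panels_[self.panel]
        self.threshold_ = self.reference_.mean_brightness
        return self

    def predict(self, cloud: ColoredPointCloud) -> np.ndarray:
        if not hasattr(self, "threshold_"):
            raise RuntimeError("FlowerThresholdClassifier is not fitted")
        if cloud.brightness is None:
            cloud = compute_brightness(cloud)
        mask, _ = classify_flower_points(cloud, self.threshold_,
                                         self.min_height)
        return mask

    def brightness_ordering_ok(self) -> bool:
        """QC: observed panel brightness follows white >= grey >= black."""
        order = [p for p in ("white", "grey", "black") if p in self.panels_]
        vals = [self.panels_[p].mean_brightness for p in order]
        return all(a >= b for a, b in zip(vals, vals[1:]))
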