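"""Core point-cloud container shared by every stage of the pipeline.

A :class:`ColoredPointCloud` is a column-oriented set of georeferenced 3D
points with 8-bit-scale RGB colors and optional derived attributes
(brightness, height above ground, semantic class label, tree assignment).
All columns are NumPy arrays of equal length; colors are kept as floats on
the [0, 255] scale so that radiometric rescaling is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# Semantic class codes, chosen to double as LAS classification codes
# (5-bit field in LAS 1.2, so all codes must stay below 32).
LABEL_UNASSIGNED = 1
LABEL_GROUND = 2
LABEL_CANOPY = 5
LABEL_PANEL = 29
LABEL_FLOWER = 30

LABEL_NAMES = {
    LABEL_UNASSIGNED: "unassigned",
    LABEL_GROUND: "ground",
    LABEL_CANOPY: "canopy",
    LABEL_PANEL: "panel",
    LABEL_FLOWER: "flower",
}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}


@dataclass
class ColoredPointCloud:
    """Colored 3D point cloud with optional per-point derived attributes.

    Parameters
    ----------
    x, y, z : ndarray of float
        Planar coordinates and elevation in metres (projected CRS).
    r, g, b : ndarray of float
        Color channels on the integer scale [0, 255]. Stored as floats so
        that illumination rescaling and brightness arithmetic are exact.
    brightness : ndarray of float, optional
        Per-point (r + g + b) / 3, unrounded.
    height_above_ground : ndarray of float, optional
        Height over the terrain model, metres.
    class_label : ndarray of uint8, optional
        Semantic class per point (see ``LABEL_*`` codes).
    tree_id : ndarray of int, optional
        Crown assignment; -1 means unassigned.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    brightness: Optional[np.ndarray] = None
    height_above_ground: Optional[np.ndarray] = None
    class_label: Optional[np.ndarray] = None
    tree_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        self.r = np.asarray(self.r, dtype=np.float64)
        self.g = np.asarray(self.g, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        n = self.x.size
        for name in ("y", "z", "r", "g", "b"):
            if getattr(self, name).size != n:
                raise ValueError(f"column {name!r} has wrong length")
        if n == 0:
            raise ValueError("point cloud must contain at least one point")
        for name in ("x", "y", "z"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in coordinate {name!r}")
        for name in ("r", "g", "b"):
            col = getattr(self, name)
            if col.min() < 0 or col.max() > 255:
                raise ValueError(f"color channel {name!r} outside [0, 255]")
        if self.class_label is not None:
            self.class_label = np.asarray(self.class_label, dtype=np.uint8)
        if self.tree_id is not None:
            self.tree_id = np.asarray(self.tree_id, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.x.size)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of planar coordinates."""
        return np.column_stack([self.x, self.y])

    def subset(self, mask: np.ndarray) -> "ColoredPointCloud":
        """Return a new cloud with the selected points (order preserved)."""
        mask = np.asarray(mask)
        kw = {}
        for name in ("brightness", "height_above_ground", "class_label", "tree_id"):
            col = getattr(self, name)
            if col is not None:
                kw[name] = col[mask]
        return ColoredPointCloud(
            self.x[mask], self.y[mask], self.z[mask],
            self.r[mask], self.g[mask], self.b[mask], **kw,
        )

    def copy(self) -> "ColoredPointCloud":
        kw = {}
        for name in ("brightness", "height_above_ground", "class_label", "tree_id"):
            col = getattr(self, name)
            if col is not None:
                kw[name] = col.copy()
        return ColoredPointCloud(
            self.x.copy(), self.y.copy(), self.z.copy(),
            self.r.copy(), self.g.copy(), self.b.copy(), **kw,
        )

    def scaled_colors(self, factor: float) -> "ColoredPointCloud":
        """Cloud with all channels multiplied by ``factor`` (clipped to 255).

        Emulates a uniform illumination change affecting scene and reference
        panels alike. Derived brightness is invalidated (recompute it).
        """
        out = self.copy()
        for name in ("r", "g", "b"):
            setattr(out, name, np.clip(getattr(out, name) * factor, 0.0, 255.0))
        out.brightness = None
        return out


def concatenate(clouds: list["ColoredPointCloud"]) -> ColoredPointCloud:
    """Stack clouds, keeping only attributes present on every input."""
    if not clouds:
        raise ValueError("nothing to concatenate")
    kw = {}
    for name in ("brightness", "height_above_ground", "class_label", "tree_id"):
        cols = [getattr(c, name) for c in clouds]
        if all(c is not None for c in cols):
            kw[name] = np.concatenate(cols)
    return ColoredPointCloud(
        np.concatenate([c.x for c in clouds]),
        np.concatenate([c.y for c in clouds]),
        np.concatenate([c.z for c in clouds]),
        np.concatenate([c.r for c in clouds]),
        np.concatenate([c.g for c in clouds]),
        np.concatenate([c.b for c in clouds]),
        **kw,
    )
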