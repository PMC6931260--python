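"""Individual tree crown delineation from the height-normalized cloud.

Crowns are isolated on a canopy height model (CHM): the canopy points are
rasterized to a max-height grid, smoothed, apexes are detected as local
maxima with a minimum mutual separation, and a marker-controlled watershed
on the inverted CHM (restricted to canopy-covered cells) partitions the
canopy into crowns. Crown polygons are the exact unions of their labelled
cells, so point-in-polygon membership and raster label lookup agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator

from .cloud import ColoredPointCloud

DEFAULT_MIN_CANOPY_HEIGHT = 0.5


@dataclass
class Crown:
    crown_id: int
    polygon: BaseGeometry
    centroid: tuple[float, float]
    point_indices: np.ndarray  # indices into the canopy cloud passed in


@dataclass
class CrownMap:
    """Delineated crowns plus the raster label image they came from."""

    crowns: list[Crown]
    label_image: np.ndarray  # 0 = background, k = crown id k
    x0: float
    y0: float
    cell_size: float

    def __len__(self) -> int:
        return len(self.crowns)

    @property
    def ids(self) -> list[int]:
        return [c.crown_id for c in self.crowns]

    def label_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Raster crown label at (x, y); 0 where no crown (or off-grid)."""
        ny, nx = self.label_image.shape
        ix = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        iy = np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        out = np.zeros(np.shape(x), dtype=self.label_image.dtype)
        out[ok] = self.label_image[iy[ok], ix[ok]]
        return out


def extract_canopy(cloud: ColoredPointCloud,
                   min_canopy_height: float = DEFAULT_MIN_CANOPY_HEIGHT,
                   ) -> ColoredPointCloud:
    """Points above the canopy height floor (requires normalized heights)."""
    if cloud.height_above_ground is None:
        raise ValueError("heights above ground are missing; run the DTM first")
    mask = cloud.height_above_ground > min_canopy_height
    if not mask.any():
        raise ValueError("no canopy: no point exceeds the canopy height floor")
    return cloud.subset(mask)


def _local_maxima(chm: np.ndarray, mask: np.ndarray, min_sep_cells: int,
                  ) -> list[tuple[int, int]]:
    """Deterministic apex cells: plateau maxima (smallest row/col per
    plateau), then greedy suppression by descending height."""
    footprint = np.ones((3, 3), dtype=bool)
    is_max = (chm >= ndimage.maximum_filter(chm, footprint=footprint)) & mask
    plateau_labels, n_plateaus = ndimage.label(is_max)
    candidates = []
    for lbl in range(1, n_plateaus + 1):
        rows, cols = np.nonzero(plateau_labels == lbl)
        k = np.lexsort((cols, rows))[0]
        candidates.append((chm[rows[k], cols[k]], rows[k], cols[k]))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    accepted: list[tuple[int, int]] = []
    for _, r, c in candidates:
        if all((r - ar) ** 2 + (c - ac) ** 2 >= min_sep_cells ** 2
               for ar, ac in accepted):
            accepted.append((r, c))
    return accepted


def delineate_crowns(canopy: ColoredPointCloud, chm_cell: float = 0.25,
                     smooth_sigma: float = 1.0,
                     min_peak_separation: float = 3.0,
                     min_crown_area: float = 0.5) -> CrownMap:
    """Segment the canopy cloud into individual crowns.

    Parameters are scaled to a 6 x 7 m orchard: 0.25 m CHM cells, apexes at
    least 3 m apart (half the along-row spacing), crowns below 0.5 m^2
    discarded.
    """
    if len(canopy) == 0:
        raise ValueError("empty canopy cloud")
    h = canopy.height_above_ground
    if h is None:
        raise ValueError("canopy cloud lacks heights above ground")
    x0 = float(canopy.x.min()) - chm_cell
    y0 = float(canopy.y.min()) - chm_cell
    nx = int(np.ceil((canopy.x.max() - x0) / chm_cell)) + 1
    ny = int(np.ceil((canopy.y.max() - y0) / chm_cell)) + 1
    ix = np.clip(((canopy.x - x0) / chm_cell).astype(int), 0, nx - 1)
    iy = np.clip(((canopy.y - y0) / chm_cell).astype(int), 0, ny - 1)
    flat = iy * nx + ix
    chm = np.zeros(ny * nx)
    np.maximum.at(chm, flat, h)
    chm = chm.reshape(ny, nx)
    mask = np.zeros((ny, nx), dtype=bool)
    mask[iy, ix] = True

    smoothed = ndimage.gaussian_filter(chm, sigma=smooth_sigma)
    min_sep_cells = max(int(round(min_peak_separation / chm_cell)), 1)
    apexes = _local_maxima(smoothed, mask, min_sep_cells)
    markers = np.zeros((ny, nx), dtype=np.int32)
    for k, (r, c) in enumerate(apexes, start=1):
        markers[r, c] = k
    labels = watershed(-smoothed, markers=markers, mask=mask)

    # drop undersized components
    min_cells = min_crown_area / chm_cell ** 2
    sizes = np.bincount(labels.ravel())
    for lbl in range(1, sizes.size):
        if 0 < sizes[lbl] < min_cells:
            labels[labels == lbl] = 0
    kept = sorted(set(np.unique(labels)) - {0})
    if not kept:
        raise ValueError("no crowns left after area filtering")
    relabel = {old: new for new, old in enumerate(kept, start=1)}
    remapped = np.zeros_like(labels)
    for old, new in relabel.items():
        remapped[labels == old] = new
    labels = remapped

    point_labels = labels[iy, ix]
    crowns = []
    for lbl in range(1, len(kept) + 1):
        members = np.flatnonzero(point_labels == lbl)
        rows, cols = np.nonzero(labels == lbl)
        cells = [box(x0 + c * chm_cell, y0 + r * chm_cell,
                     x0 + (c + 1) * chm_cell, y0 + (r + 1) * chm_cell)
                 for r, c in zip(rows, cols)]
        polygon = shapely.unary_union(cells)
        if members.size:
            centroid = (float(canopy.x[members].mean()),
                        float(canopy.y[members].mean()))
        else:
            centroid = (polygon.centroid.x, polygon.centroid.y)
        crowns.append(Crown(crown_id=lbl, polygon=polygon, centroid=centroid,
                            point_indices=members))
    return CrownMap(crowns=crowns, label_image=labels, x0=x0, y0=y0,
                    cell_size=chm_cell)


def assign_points(cloud: ColoredPointCloud, crowns: CrownMap,
                  min_canopy_height: float = DEFAULT_MIN_CANOPY_HEIGHT,
                  ) -> ColoredPointCloud:
    """Attach crown ids to the points inside crown footprints.

    A point gets a crown id when its (x, y) cell carries that crown's label
    and its height exceeds the canopy floor; all other points stay
    unassigned (-1).
    """
    if cloud.height_above_ground is None:
        raise ValueError("heights above ground are missing")
    out = cloud.copy()
    labels = crowns.label_at(out.x, out.y).astype(np.int64)
    labels[out.height_above_ground <= min_canopy_height] = 0
    out.tree_id = np.where(labels > 0, labels, -1)
    return out


class CrownSegmenter(BaseEstimator):
    """Crown delineation with a fit/predict interface.

    ``fit`` delineates crowns on a height-normalized cloud (fitted result in
    ``crowns_``); ``predict`` returns per-point crown ids (-1 unassigned).
    """

    def __init__(self, chm_cell: float = 0.25, smooth_sigma: float = 1.0,
                 min_peak_separation: float = 3.0, min_crown_area: float = 0.5,
                 min_canopy_height: float = DEFAULT_MIN_CANOPY_HEIGHT):
        self.chm_cell = chm_cell
        self.smooth_sigma = smooth_sigma
        self.min_peak_separation = min_peak_separation
        self.min_crown_area = min_crown_area
        self.min_canopy_height = min_canopy_height

    def fit(self, cloud: ColoredPointCloud, y=None) -> "CrownSegmenter":
        canopy = extract_canopy(cloud, self.min_canopy_height)
        self.crowns_ = delineate_crowns(
            canopy, chm_cell=self.chm_cell, smooth_sigma=self.smooth_sigma,
            min_peak_separation=self.min_peak_separation,
            min_crown_area=self.min_crown_area)
        return self

    def predict(self, cloud: ColoredPointCloud) -> np.ndarray:
        if not hasattr(self, "crowns_"):
            raise RuntimeError("CrownSegmenter is not fitted")
        return assign_points(cloud, self.crowns_,
                             self.min_canopy_height).tree_id

    def fit_predict(self, cloud: ColoredPointCloud, y=None) -> np.ndarray:
        return self.fit(cloud).predict(cloud)
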