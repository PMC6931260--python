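"""Digital terrain model generation and height normalization.

The DTM is a regular grid of ground elevations estimated from the cloud in
three deterministic passes:

1. per-cell low quantile of z (default 5th percentile) as a provisional
   ground surface;
2. rejection of cells whose provisional value sits well above a grey-opening
   (minimum-then-maximum filter) of the provisional grid — these are cells
   dominated by canopy returns, e.g. directly under a dense crown — followed
   by nearest-neighbour filling and a 3x3 mean smoothing applied to the
   filled cells only;
3. a refinement pass that averages, per cell, the z of the points lying
   within ``refine_dz`` of the provisional surface. This removes the
   low-quantile bias (on a 10% slope a plain 5th percentile over a 2 m cell
   is systematically ~0.09 m low) while still rejecting canopy returns.

Heights above ground are obtained by bilinear interpolation between cell
centres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .cloud import ColoredPointCloud


@dataclass
class DTMGrid:
    """Regular grid of ground elevations (cell-centre registered)."""

    x0: float
    y0: float
    cell_size: float
    elevations: np.ndarray  # shape (ny, nx), row i covers y0 + i*cell

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevations.shape

    def interpolate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear ground elevation at (x, y); errors outside the grid."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        ny, nx = self.elevations.shape
        if (np.any(x < self.x0) or np.any(x > self.x0 + nx * self.cell_size)
                or np.any(y < self.y0) or np.any(y > self.y0 + ny * self.cell_size)):
            raise ValueError("point outside the DTM grid extent")
        # continuous cell-centre coordinates, clamped at the border half-cell
        cx = np.clip((x - self.x0) / self.cell_size - 0.5, 0, nx - 1)
        cy = np.clip((y - self.y0) / self.cell_size - 0.5, 0, ny - 1)
        return ndimage.map_coordinates(self.elevations, [cy, cx], order=1,
                                       mode="nearest")

    def to_ascii_grid(self, path) -> None:
        """Export as an ESRI ASCII grid (.asc)."""
        ny, nx = self.elevations.shape
        header = (
            f"ncols {nx}\nnrows {ny}\nxllcorner {self.x0}\nyllcorner {self.y0}\n"
            f"cellsize {self.cell_size}\nNODATA_value -9999\n"
        )
        # .asc rows run north to south
        body = "\n".join(
            " ".join(f"{v:.4f}" for v in row) for row in self.elevations[::-1]
        )
        Path(path).write_text(header + body + "\n")


def generate_dtm(cloud: ColoredPointCloud, cell_size: float = 2.0,
                 quantile: float = 0.05, refine_dz: float = 0.25,
                 reject_dz: float = 0.5) -> DTMGrid:
    """Estimate the ground surface under the cloud.

    Parameters
    ----------
    cell_size : float
        Grid cell, metres. In a 6 x 7 m orchard ground is visible between
        crowns at 2 m. If the cloud holds fewer points than cells the cell
        size is coarsened automatically (with a warning).
    quantile : float
        Low quantile of z per cell used for the provisional surface.
    refine_dz : float
        Half-band around the provisional surface within which points are
        accepted as ground for the refinement mean.
    reject_dz : float
        Cells whose provisional value exceeds the 5x5 grey-opening of the
        grid by more than this are treated as canopy-contaminated and
        interpolated from their neighbours instead.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    n = len(cloud)
    xmin, xmax = cloud.x.min(), cloud.x.max()
    ymin, ymax = cloud.y.min(), cloud.y.max()
    width = max(xmax - xmin, cell_size * 1e-6)
    depth = max(ymax - ymin, cell_size * 1e-6)

    def grid_dims(cs):
        return max(int(np.ceil(depth / cs)), 1), max(int(np.ceil(width / cs)), 1)

    ny, nx = grid_dims(cell_size)
    if n < nx * ny:
        coarser = float(np.sqrt(4.0 * width * depth / n))
        warnings.warn(
            f"cloud has {n} points for {nx * ny} DTM cells; "
            f"coarsening cell size to {coarser:.2f} m", stacklevel=2)
        cell_size = coarser
        ny, nx = grid_dims(cell_size)

    ix = np.clip(((cloud.x - xmin) / cell_size).astype(int), 0, nx - 1)
    iy = np.clip(((cloud.y - ymin) / cell_size).astype(int), 0, ny - 1)
    flat = iy * nx + ix

    # provisional: per-cell low quantile of z
    order = np.argsort(flat, kind="stable")
    sorted_cells = flat[order]
    sorted_z = cloud.z[order]
    boundaries = np.flatnonzero(np.diff(sorted_cells)) + 1
    groups = np.split(sorted_z, boundaries)
    cells_present = sorted_cells[np.concatenate([[0], boundaries])] if n else []
    prov = np.full(ny * nx, np.nan)
    for cell, zs in zip(cells_present, groups):
        prov[cell] = np.quantile(zs, quantile)
    prov = prov.reshape(ny, nx)

    empty = ~np.isfinite(prov)
    # canopy rejection: provisional values far above the local opened surface
    filled_for_open = prov.copy()
    if empty.any():
        # temporary nearest fill so the morphological pass is defined everywhere
        idx = ndimage.distance_transform_edt(empty, return_distances=False,
                                             return_indices=True)
        filled_for_open = filled_for_open[tuple(idx)]
    opened = ndimage.grey_dilation(ndimage.grey_erosion(filled_for_open, size=5),
                                   size=5)
    rejected = (filled_for_open - opened) > reject_dz
    invalid = empty | rejected

    elev = prov.copy()
    elev[invalid] = np.nan
    if np.all(np.isnan(elev)):
        raise ValueError("no valid ground cells found")
    if invalid.any():
        idx = ndimage.distance_transform_edt(np.isnan(elev),
                                             return_distances=False,
                                             return_indices=True)
        elev = elev[tuple(idx)]
        smoothed = ndimage.uniform_filter(elev, size=3, mode="nearest")
        elev = np.where(invalid, smoothed, elev)

    dtm = DTMGrid(x0=float(xmin), y0=float(ymin), cell_size=float(cell_size),
                  elevations=elev)

    # refinement: per-cell mean z of near-surface points, iterated so cells
    # first filled by interpolation (e.g. under crowns) converge onto the
    # ground points they do contain
    near = np.zeros(n, dtype=bool)
    for _ in range(3):
        surface_at_points = dtm.interpolate(cloud.x, cloud.y)
        near = np.abs(cloud.z - surface_at_points) <= refine_dz
        if not near.any():
            break
        sums = np.bincount(flat[near], weights=cloud.z[near], minlength=ny * nx)
        counts = np.bincount(flat[near], minlength=ny * nx)
        refined = np.divide(sums, counts, out=np.full(ny * nx, np.nan),
                            where=counts > 0).reshape(ny, nx)
        keep = np.isfinite(refined)
        elev = np.where(keep, refined, elev)
        dtm = DTMGrid(x0=dtm.x0, y0=dtm.y0, cell_size=dtm.cell_size,
                      elevations=elev)
    if near.any():
        elev = _plane_fit_elevations(cloud, near, flat, elev, xmin, ymin,
                                     cell_size, ny, nx)
        dtm = DTMGrid(x0=dtm.x0, y0=dtm.y0, cell_size=dtm.cell_size,
                      elevations=elev)
    return dtm


def _plane_fit_elevations(cloud, near, flat, elev, xmin, ymin, cell_size,
                          ny, nx):
    """Per-cell ground elevation from a local plane fit.

    Fits z ~ 1 + x + y over the selected ground points of each cell's 3x3
    neighbourhood and evaluates at the cell centre. This removes the bias of
    a plain per-cell mean in partially covered border cells on sloped
    ground. Cells whose neighbourhood is ill-conditioned (too few or
    near-collinear ground points) keep their iterative-mean value.
    """
    # local coordinates keep the normal equations well conditioned
    px = (cloud.x - xmin)[near]
    py = (cloud.y - ymin)[near]
    pz = cloud.z[near]
    cells = flat[near]
    size = ny * nx

    def acc(values):
        return np.bincount(cells, weights=values, minlength=size)

    moments = np.stack([
        acc(np.ones_like(px)), acc(px), acc(py), acc(pz),
        acc(px * px), acc(px * py), acc(py * py), acc(px * pz), acc(py * pz),
    ]).reshape(9, ny, nx)
    # 3x3 neighbourhood sums (edge cells reuse the border row/column)
    nb = np.stack([ndimage.uniform_filter(m, size=3, mode="nearest") * 9
                   for m in moments])
    n_pts, sx, sy, sz, sxx, sxy, syy, sxz, syz = nb.reshape(9, -1)
    cx = ((np.arange(size) % nx) + 0.5) * cell_size
    cy = ((np.arange(size) // nx) + 0.5) * cell_size
    A = np.empty((size, 3, 3))
    A[:, 0, 0] = n_pts
    A[:, 0, 1] = A[:, 1, 0] = sx - n_pts * cx
    A[:, 0, 2] = A[:, 2, 0] = sy - n_pts * cy
    A[:, 1, 1] = sxx - 2 * cx * sx + n_pts * cx ** 2
    A[:, 1, 2] = A[:, 2, 1] = sxy - cx * sy - cy * sx + n_pts * cx * cy
    A[:, 2, 2] = syy - 2 * cy * sy + n_pts * cy ** 2
    b = np.stack([sz, sxz - cx * sz, syz - cy * sz], axis=1)
    out = elev.ravel().copy()
    dets = np.linalg.det(A)
    # scale-aware conditioning guard; fall back to the mean value otherwise
    good = (n_pts >= 8) & (np.abs(dets) > 1e-9 * np.maximum(n_pts, 1) ** 3)
    if good.any():
        beta = np.linalg.solve(A[good], b[good][:, :, None])
        out[good] = beta[:, 0, 0]
    return out.reshape(ny, nx)


def normalize_heights(cloud: ColoredPointCloud, dtm: DTMGrid) -> ColoredPointCloud:
    """Attach ``height_above_ground = z - DTM(x, y)`` to every point."""
    out = cloud.copy()
    out.height_above_ground = out.z - dtm.interpolate(out.x, out.y)
    return out


class TerrainModel(BaseEstimator):
    """Ground-surface estimator with a fit/transform interface.

    ``fit`` builds the DTM from a cloud; ``transform`` attaches heights
    above ground to any cloud over the same extent.
    """

    def __init__(self, cell_size: float = 2.0, quantile: float = 0.05,
                 refine_dz: float = 0.25, reject_dz: float = 0.5):
        self.cell_size = cell_size
        self.quantile = quantile
        self.refine_dz = refine_dz
        self.reject_dz = reject_dz

    def fit(self, cloud: ColoredPointCloud, y=None) -> "TerrainModel":
        self.dtm_ = generate_dtm(cloud, cell_size=self.cell_size,
                                 quantile=self.quantile,
                                 refine_dz=self.refine_dz,
                                 reject_dz=self.reject_dz)
        return self

    def transform(self, cloud: ColoredPointCloud) -> ColoredPointCloud:
        if not hasattr(self, "dtm_"):
            raise RuntimeError("TerrainModel is not fitted")
        return normalize_heights(cloud, self.dtm_)

    def fit_transform(self, cloud: ColoredPointCloud, y=None) -> ColoredPointCloud:
        return self.fit(cloud).transform(cloud)
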