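"""Point-cloud and field-vector I/O.

Clouds are read and written either as uncompressed LAS 1.2 with RGB or as
plain-text ``xyzrgb`` (six whitespace-separated columns, ``#`` comments).
Field boundaries are GeoJSON polygons; only the ring coordinates are kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import shape as _geojson_shape
from shapely.geometry.base import BaseGeometry

from ._las import read_las, write_las
from .cloud import ColoredPointCloud


@dataclass(frozen=True)
class FieldBoundary:
    """Closed planar polygon delimiting the studied field."""

    polygon: BaseGeometry
    name: str = ""

    def __post_init__(self) -> None:
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise ValueError("field boundary must enclose a positive area")
        if not self.polygon.is_valid:
            raise ValueError("field boundary polygon is invalid (self-intersecting?)")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".las":
        return "las"
    if suffix in (".xyz", ".txt", ".xyzrgb"):
        return "xyzrgb"
    raise ValueError(f"cannot infer point-cloud format from {path.name!r}")


def read_cloud(path, fmt: str | None = None) -> ColoredPointCloud:
    """Read a colored point cloud from LAS or xyzrgb text.

    Colors are normalized to the [0, 255] scale (16-bit LAS channels are
    divided by 257) and point order is preserved.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "las":
        return read_las(path)
    if fmt == "xyzrgb":
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty files handled below
            data = np.loadtxt(path, comments="#", ndmin=2)
        if data.size == 0:
            raise ValueError(f"{path}: empty point cloud")
        if data.shape[1] < 6:
            raise ValueError(
                f"{path}: expected 6 columns x y z r g b, found {data.shape[1]}"
            )
        x, y, z, r, g, b = data[:, :6].T
        if max(r.max(), g.max(), b.max()) > 255:
            raise ValueError(f"{path}: color channels exceed the 8-bit range")
        return ColoredPointCloud(x, y, z, r, g, b)
    raise ValueError(f"unknown point-cloud format {fmt!r}")


def write_cloud(cloud: ColoredPointCloud, path, fmt: str | None = None) -> None:
    """Write a cloud as LAS (classification carries class labels) or text."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "las":
        write_las(cloud, path)
        return
    if fmt == "xyzrgb":
        arr = np.column_stack([
            cloud.x, cloud.y, cloud.z,
            np.round(cloud.r), np.round(cloud.g), np.round(cloud.b),
        ])
        try:
            np.savetxt(path, arr, fmt="%.4f %.4f %.4f %d %d %d",
                       header="x y z r g b")
        except OSError as exc:
            raise OSError(f"cannot write {path}: {exc}") from exc
        return
    raise ValueError(f"unknown point-cloud format {fmt!r}")


def read_boundary(path, name: str | None = None) -> FieldBoundary:
    """Read a field boundary polygon from GeoJSON."""
    path = Path(path)
    obj = json.loads(path.read_text())
    geom = _extract_geometry(obj)
    return FieldBoundary(polygon=geom, name=name or path.stem)


def _extract_geometry(obj: dict) -> BaseGeometry:
    t = obj.get("type")
    if t == "FeatureCollection":
        geoms = [_geojson_shape(f["geometry"]) for f in obj["features"]]
        return shapely.unary_union(geoms)
    if t == "Feature":
        return _geojson_shape(obj["geometry"])
    return _geojson_shape(obj)


def write_boundary(boundary: FieldBoundary, path) -> None:
    geojson = {
        "type": "Feature",
        "properties": {"name": boundary.name},
        "geometry": json.loads(shapely.to_geojson(boundary.polygon)),
    }
    Path(path).write_text(json.dumps(geojson))


def crop_to_boundary(cloud: ColoredPointCloud,
                     boundary: FieldBoundary) -> ColoredPointCloud:
    """Keep exactly the points whose (x, y) fall inside or on the polygon."""
    inside = shapely.intersects_xy(boundary.polygon, cloud.x, cloud.y)
    if not inside.any():
        raise ValueError(
            "no points inside the field boundary — check that the boundary "
            "and the cloud share the same coordinate reference system"
        )
    return cloud.subset(inside)
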