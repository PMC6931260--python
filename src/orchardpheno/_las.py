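"""Minimal LAS 1.2 codec for RGB point clouds.

Supports exactly what the pipeline needs: reading point data formats 2 and 3
(XYZ + RGB, format 3 adds GPS time) and writing format 2. Coordinates are
stored with the usual scaled-integer encoding (1 mm resolution); colors are
stored as 16-bit channels (8-bit value x 257, so 255 maps to 65535), and the
point classification field carries the semantic class code.

This is a deliberately small reader/writer for the uncompressed LAS subset
used here — not a general LAS library. LAZ is not supported.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .cloud import ColoredPointCloud, LABEL_UNASSIGNED

_HEADER_SIZE = 227  # LAS 1.2 public header block
_HEADER_FMT = "<4sHH LHH 8s BB 32s32s HH HLL B H L 5L 12d"

_POINT_DTYPE_2 = np.dtype([
    ("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"),
    ("intensity", "<u2"), ("flags", "u1"), ("classification", "u1"),
    ("scan_angle", "i1"), ("user_data", "u1"), ("point_source", "<u2"),
    ("red", "<u2"), ("green", "<u2"), ("blue", "<u2"),
])
_POINT_DTYPE_3 = np.dtype([
    ("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"),
    ("intensity", "<u2"), ("flags", "u1"), ("classification", "u1"),
    ("scan_angle", "i1"), ("user_data", "u1"), ("point_source", "<u2"),
    ("gps_time", "<f8"),
    ("red", "<u2"), ("green", "<u2"), ("blue", "<u2"),
])

_SCALE = 0.001  # metres; millimetre coordinate resolution


def read_las(path) -> ColoredPointCloud:
    """Read an uncompressed LAS file with RGB (point formats 2 or 3)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_SIZE or raw[:4] != b"LASF":
        raise ValueError(f"{path}: not a LAS file (bad signature)")
    fields = struct.unpack(_HEADER_FMT, raw[:_HEADER_SIZE])
    point_format = fields[16] & 0x3F  # mask potential LAZ compression bit
    record_length = fields[17]
    n_points = fields[18]
    offset_to_points = fields[14]
    scales = fields[24:27]
    offsets = fields[27:30]
    if point_format == 2:
        dtype = _POINT_DTYPE_2
    elif point_format == 3:
        dtype = _POINT_DTYPE_3
    else:
        raise ValueError(
            f"{path}: LAS point format {point_format} has no RGB channels "
            "(only formats 2 and 3 are supported)"
        )
    if record_length < dtype.itemsize:
        raise ValueError(f"{path}: point record length {record_length} too short")
    if n_points == 0:
        raise ValueError(f"{path}: empty point cloud")
    buf = raw[offset_to_points:offset_to_points + n_points * record_length]
    if record_length == dtype.itemsize:
        pts = np.frombuffer(buf, dtype=dtype, count=n_points)
    else:  # extra per-point bytes: view row-wise
        rows = np.frombuffer(buf, dtype=np.uint8).reshape(n_points, record_length)
        pts = rows[:, : dtype.itemsize].copy().view(dtype).reshape(n_points)
    x = pts["X"] * scales[0] + offsets[0]
    y = pts["Y"] * scales[1] + offsets[1]
    z = pts["Z"] * scales[2] + offsets[2]
    r = pts["red"].astype(np.float64)
    g = pts["green"].astype(np.float64)
    b = pts["blue"].astype(np.float64)
    # 16-bit color heuristic: any channel beyond 8-bit range implies the
    # common 16-bit convention; 257 maps 65535 back to 255 exactly.
    if max(r.max(), g.max(), b.max()) > 255:
        r = np.floor_divide(r, 257)
        g = np.floor_divide(g, 257)
        b = np.floor_divide(b, 257)
    labels = (pts["classification"] & 0x1F).astype(np.uint8)
    return ColoredPointCloud(x, y, z, r, g, b, class_label=labels)


def write_las(cloud: ColoredPointCloud, path) -> None:
    """Write the cloud as LAS 1.2, point format 2 (XYZ + RGB)."""
    path = Path(path)
    n = len(cloud)
    offx, offy, offz = cloud.x.min(), cloud.y.min(), cloud.z.min()
    pts = np.zeros(n, dtype=_POINT_DTYPE_2)
    pts["X"] = np.round((cloud.x - offx) / _SCALE).astype(np.int64)
    pts["Y"] = np.round((cloud.y - offy) / _SCALE).astype(np.int64)
    pts["Z"] = np.round((cloud.z - offz) / _SCALE).astype(np.int64)
    pts["flags"] = 0b00001001  # single return, first of one
    if cloud.class_label is not None:
        pts["classification"] = cloud.class_label & 0x1F
    else:
        pts["classification"] = LABEL_UNASSIGNED
    # store 8-bit colors on the 16-bit scale
    pts["red"] = (np.round(cloud.r).astype(np.uint32) * 257).astype(np.uint16)
    pts["green"] = (np.round(cloud.g).astype(np.uint32) * 257).astype(np.uint16)
    pts["blue"] = (np.round(cloud.b).astype(np.uint32) * 257).astype(np.uint16)
    header = struct.pack(
        _HEADER_FMT,
        b"LASF", 0, 0,                       # signature, source id, encoding
        0, 0, 0, b"\0" * 8,                  # project GUID
        1, 2,                                # version 1.2
        b"orchardpheno".ljust(32, b"\0"),    # system identifier
        b"orchardpheno".ljust(32, b"\0"),    # generating software
        0, 0,                                # creation day / year
        _HEADER_SIZE, _HEADER_SIZE, 0,       # header size, point offset, n VLRs
        2, _POINT_DTYPE_2.itemsize,          # point format, record length
        n, n, 0, 0, 0, 0,                    # n points, n by return (5)
        _SCALE, _SCALE, _SCALE,
        offx, offy, offz,
        cloud.x.max(), offx, cloud.y.max(), offy, cloud.z.max(), offz,
    )
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(pts.tobytes())
    except OSError as exc:
        raise OSError(f"cannot write LAS file {path}: {exc}") from exc
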