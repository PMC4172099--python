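"""Reading and writing ImageJ ROI files (.roi and .zip bundles).

Implements the subset of the ImageJ binary ROI format needed here:
polygon, freehand, rectangle, and oval subtypes. Other subtypes (line,
point, ...) raise :class:`UnsupportedRoiType` naming the offending kind.

Coordinate conventions: ImageJ integer coordinates sit at pixel corners,
with pixel (x, y) spanning [x, x+1) x [y, y+1). Polygon and freehand
vertices are imported verbatim as (x, y) floats, so an exported polygon
round-trips exactly. Rectangles and ovals, whose ImageJ semantics are
"cover w x h whole pixels", are shifted by -0.5 so that the covered pixel
centers under this package's center-in-polygon rule are exactly those
w x h pixels.
"""

from __future__ import annotations

import os
import struct
import zipfile

import numpy as np

from .rois import Roi, RoiList

_MAGIC = b"Iout"

_TYPE_NAMES = {
    0: "polygon", 1: "rect", 2: "oval", 3: "line", 4: "freeline",
    5: "polyline", 6: "noRoi", 7: "freehand", 8: "traced", 9: "angle",
    10: "point",
}


class UnsupportedRoiType(ValueError):
    """Raised for ImageJ ROI subtypes this reader does not handle."""


def _decode(data: bytes, label: str | None, im_shape) -> Roi:
    if data[:4] != _MAGIC:
        raise ValueError("not an ImageJ ROI file (bad magic)")
    roi_type = data[6]
    name = _TYPE_NAMES.get(roi_type, f"type {roi_type}")
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    n = struct.unpack(">H", data[16:18])[0]
    if roi_type == 1:  # rectangle
        w, h = right - left, bottom - top
        verts = np.array([(left, top), (right, top),
                          (right, bottom), (left, bottom)], dtype=float) - 0.5
        return Roi(polygons=[verts], label=label, im_shape=im_shape)
    if roi_type == 2:  # oval inscribed in the bounding box
        cx = (left + right) / 2.0 - 0.5
        cy = (top + bottom) / 2.0 - 0.5
        a = (right - left) / 2.0  # semi-axis along x
        b = (bottom - top) / 2.0
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        verts = np.column_stack((cx + a * np.cos(theta),
                                 cy + b * np.sin(theta)))
        return Roi(polygons=[verts], label=label, im_shape=im_shape)
    if roi_type in (0, 7):  # polygon, freehand
        xs = np.frombuffer(data, dtype=">i2", count=n, offset=64) + left
        ys = np.frombuffer(data, dtype=">i2", count=n, offset=64 + 2 * n) + top
        verts = np.column_stack((xs, ys)).astype(float)
        return Roi(polygons=[verts], label=label, im_shape=im_shape)
    raise UnsupportedRoiType(f"unsupported ImageJ ROI subtype: {name}")


def read_imagej(path, im_shape=None) -> RoiList:
    """Read a single .roi file or a .zip of ROIs into a :class:`RoiList`.

    Labels come from the zip entry names (or the file stem for a lone
    .roi). ``im_shape`` should be supplied so the ROIs can rasterize.
    """
    path = os.fspath(path)
    rois = []
    if path.lower().endswith(".zip"):
        with zipfile.ZipFile(path) as zf:
            for entry in zf.namelist():
                if not entry.lower().endswith(".roi"):
                    continue
                label = os.path.splitext(os.path.basename(entry))[0]
                rois.append(_decode(zf.read(entry), label, im_shape))
    else:
        label = os.path.splitext(os.path.basename(path))[0]
        with open(path, "rb") as f:
            rois.append(_decode(f.read(), label, im_shape))
    return RoiList(rois, name=os.path.splitext(os.path.basename(path))[0])


def _encode_polygon(vertices: np.ndarray) -> bytes:
    """Encode one polygon as an ImageJ polygon ROI record."""
    verts = np.asarray(vertices)
    xs = np.round(verts[:, 0]).astype(int)
    ys = np.round(verts[:, 1]).astype(int)
    left, top = int(xs.min()), int(ys.min())
    right, bottom = int(xs.max()), int(ys.max())
    n = len(xs)
    header = bytearray(64)
    header[0:4] = _MAGIC
    struct.pack_into(">h", header, 4, 227)  # format version
    header[6] = 0  # polygon
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">H", header, 16, n)
    body = (np.asarray(xs - left, dtype=">i2").tobytes()
            + np.asarray(ys - top, dtype=">i2").tobytes())
    return bytes(header) + body


def write_imagej(roi_list: RoiList, path) -> None:
    """Write polygon ROIs to an ImageJ-compatible .zip (or single .roi).

    Vertices are rounded to integers (the format stores 16-bit integer
    coordinates). Only single-polygon ROIs are written per entry; an ROI
    with several polygons produces several entries.
    """
    path = os.fspath(path)
    records = []
    for i, roi in enumerate(roi_list):
        if roi.polygons is None:
            raise ValueError("only polygon ROIs can be written to ImageJ format")
        base = roi.label or f"roi_{i:04d}"
        for j, poly in enumerate(roi.polygons):
            name = base if len(roi.polygons) == 1 else f"{base}_{j}"
            records.append((name, _encode_polygon(poly)))
    if path.lower().endswith(".zip"):
        with zipfile.ZipFile(path, "w") as zf:
            for name, blob in records:
                zf.writestr(f"{name}.roi", blob)
    else:
        if len(records) != 1:
            raise ValueError("a single .roi file holds exactly one polygon")
        with open(path, "wb") as f:
            f.write(records[0][1])
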