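"""Reading ImageJ ROI archives into label masks.

Experts commonly annotate fluorescent features in ImageJ/Fiji and export the
outlines as ``.roi`` files or ``RoiSet.zip`` archives.  This module decodes
the documented binary ``.roi`` layout (big-endian, magic ``Iout``) for the
closed-outline subtypes — rectangle, oval, polygon, freehand and traced —
and rasterizes each outline to one labeled object.

Rasterization rule: a pixel belongs to an ROI when its center
``(row + 0.5, col + 0.5)`` lies inside the outline (for rectangles this
reproduces ImageJ's ``width x height`` pixel count exactly).  Overlapping
ROIs within one archive are resolved last-writer-wins, with a warning.

A minimal writer is provided so synthetic annotations can round-trip
through the same format.
"""

from __future__ import annotations

import struct
import warnings
import zipfile
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath

from .io import LabelMask, relabel

__all__ = ["read_imagej_rois", "decode_roi", "encode_polygon_roi", "encode_rect_roi"]

_MAGIC = b"Iout"

# ImageJ ROI type codes (byte 6 of the header).
_POLYGON, _RECT, _OVAL, _LINE, _FREELINE, _POLYLINE, _NOROI, _FREEHAND, _TRACED = range(9)
_CLOSED_TYPES = {_POLYGON, _RECT, _OVAL, _FREEHAND, _TRACED}


def decode_roi(data: bytes) -> dict:
    """Decode one ``.roi`` blob into a dict with keys type/top/left/bottom/right
    and, for polygonal types, ``vertices`` as an (n, 2) array of (row, col)."""
    if data[:4] != _MAGIC:
        raise ValueError("not an ImageJ ROI (missing 'Iout' magic)")
    roi_type = data[6]
    top, left, bottom, right, n = struct.unpack(">hhhhh", data[8:18])
    out = {"type": roi_type, "top": top, "left": left, "bottom": bottom, "right": right}
    if roi_type in (_POLYGON, _FREEHAND, _TRACED):
        xs = np.frombuffer(data, dtype=">i2", count=n, offset=64).astype(int) + left
        ys = np.frombuffer(data, dtype=">i2", count=n, offset=64 + 2 * n).astype(int) + top
        out["vertices"] = np.column_stack([ys, xs])  # (row, col)
    return out


def _rasterize(roi: dict, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    t, l, b, r = roi["top"], roi["left"], roi["bottom"], roi["right"]
    if roi["type"] == _RECT:
        mask[max(t, 0) : min(b, h), max(l, 0) : min(r, w)] = True
        return mask
    if roi["type"] == _OVAL:
        cy, cx = (t + b) / 2.0, (l + r) / 2.0
        ry, rx = (b - t) / 2.0, (r - l) / 2.0
        rows = np.arange(max(t, 0), min(b, h))
        cols = np.arange(max(l, 0), min(r, w))
        if not len(rows) or not len(cols):
            return mask
        yy, xx = np.meshgrid(rows + 0.5, cols + 0.5, indexing="ij")
        inside = ((yy - cy) / max(ry, 1e-9)) ** 2 + ((xx - cx) / max(rx, 1e-9)) ** 2 <= 1.0
        mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1] = inside
        return mask
    # polygonal subtypes: pixel-center containment
    verts = roi["vertices"]
    if len(verts) < 3:
        return mask
    rows = np.arange(max(t - 1, 0), min(b + 1, h))
    cols = np.arange(max(l - 1, 0), min(r + 1, w))
    if not len(rows) or not len(cols):
        return mask
    yy, xx = np.meshgrid(rows + 0.5, cols + 0.5, indexing="ij")
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    path = MplPath(verts)
    inside = path.contains_points(pts).reshape(len(rows), len(cols))
    mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1] = inside
    return mask


def read_imagej_rois(
    path: str | Path, shape: tuple[int, int], annotator_id: str = ""
) -> LabelMask:
    """Read a ``.roi`` file or ``.zip`` archive and rasterize into a LabelMask.

    Unsupported ROI subtypes (lines, points, ...) are skipped with a per-ROI
    warning; an empty archive yields an empty mask.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    blobs: list[tuple[str, bytes]] = []
    if path.suffix.lower() == ".zip":
        with zipfile.ZipFile(path) as zf:
            for name in zf.namelist():
                if name.lower().endswith(".roi"):
                    blobs.append((name, zf.read(name)))
    else:
        blobs.append((path.name, path.read_bytes()))

    labels = np.zeros(shape, dtype=np.int32)
    nxt = 1
    for name, blob in blobs:
        roi = decode_roi(blob)
        if roi["type"] not in _CLOSED_TYPES:
            warnings.warn(f"{name}: unsupported ROI subtype {roi['type']}, skipped", stacklevel=2)
            continue
        mask = _rasterize(roi, shape)
        if not mask.any():
            warnings.warn(f"{name}: ROI rasterized to zero pixels, skipped", stacklevel=2)
            continue
        if (labels[mask] > 0).any():
            warnings.warn(
                f"{name}: overlaps a previous ROI; last writer wins", stacklevel=2
            )
        labels[mask] = nxt
        nxt += 1
    return relabel(LabelMask(labels, annotator_id=annotator_id or path.stem))


def _header(roi_type: int, top: int, left: int, bottom: int, right: int, n: int) -> bytearray:
    buf = bytearray(64)
    buf[0:4] = _MAGIC
    struct.pack_into(">h", buf, 4, 228)  # version
    buf[6] = roi_type
    struct.pack_into(">hhhhh", buf, 8, top, left, bottom, right, n)
    return buf


def encode_rect_roi(top: int, left: int, bottom: int, right: int) -> bytes:
    """Encode a rectangle covering rows top..bottom-1, cols left..right-1."""
    return bytes(_header(_RECT, top, left, bottom, right, 0))


def encode_polygon_roi(vertices: np.ndarray) -> bytes:
    """Encode a closed polygon from (row, col) integer vertices."""
    verts = np.asarray(vertices, dtype=int)
    rows, cols = verts[:, 0], verts[:, 1]
    top, left = int(rows.min()), int(cols.min())
    bottom, right = int(rows.max()), int(cols.max())
    buf = _header(_POLYGON, top, left, bottom, right, len(verts))
    buf += np.asarray(cols - left, dtype=">i2").tobytes()
    buf += np.asarray(rows - top, dtype=">i2").tobytes()
    return bytes(buf)
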