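"""Core data model and mask/image I/O.

The pipeline's currency is a trio of 2-D rasters: a grayscale intensity
image (:class:`Image2D`), a dense instance label grid (:class:`LabelMask`,
0 = background, k > 0 = object id) and a boolean analysis region
(:class:`RegionMask`).  Objects are maximal 8-connected pixel sets;
coordinates are 0-based ``(row, col)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from imageio import v3 as iio
from scipy import ndimage

__all__ = [
    "Image2D",
    "LabelMask",
    "RegionMask",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "connected_components",
    "filter_min_size",
    "relabel",
    "max_project",
]

# 8-connectivity: horizontal, vertical and diagonal neighbours.
STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass
class Image2D:
    """Single-channel 2-D intensity image.

    Parameters
    ----------
    pixels : ndarray
        Non-negative intensities, shape ``(H, W)``.
    bit_depth : int
        8, 12 or 16; all intensities must lie in ``[0, 2**bit_depth - 1]``.
    px_per_um : float or None
        Lateral sampling in pixels per micrometer (e.g. 1.61 px/µm for the
        confocal acquisitions this package targets).  Required only when
        physical-area quantification is requested.
    id : str
        Opaque identifier, usually the file stem.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    px_per_um: float | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"Image2D requires a 2-D array, got shape {self.pixels.shape}")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"bit_depth must be 8, 12 or 16, got {self.bit_depth}")
        if self.pixels.size and (
            self.pixels.min() < 0 or self.pixels.max() > 2**self.bit_depth - 1
        ):
            raise ValueError("intensities outside [0, 2**bit_depth - 1]")
        if self.px_per_um is not None and not self.px_per_um > 0:
            raise ValueError("px_per_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMask:
    """Dense instance segmentation: 0 background, 1..K object ids."""

    labels: np.ndarray
    annotator_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"LabelMask requires a 2-D array, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.issubdtype(self.labels.dtype, np.bool_):
                self.labels = connected_components(self.labels).labels
            else:
                raise ValueError("labels must be integer (or boolean, auto-instanced)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_objects(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def ids(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]

    def binary(self) -> np.ndarray:
        return self.labels > 0

    def areas(self) -> np.ndarray:
        """Pixel area per object, indexed 0..K-1 for ids 1..K."""
        return np.bincount(self.labels.ravel(), minlength=self.n_objects + 1)[1:]

    def centroids(self) -> np.ndarray:
        """(K, 2) array of (row, col) centroids for ids 1..K."""
        if self.n_objects == 0:
            return np.empty((0, 2))
        return np.asarray(
            ndimage.center_of_mass(self.binary(), self.labels, np.arange(1, self.n_objects + 1))
        )


@dataclass
class RegionMask:
    """Boolean analysis region (e.g. the NeuN-positive cell layer)."""

    mask: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("RegionMask requires a 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def _infer_bit_depth(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype in (np.uint16, np.int16):
        return 16
    if np.issubdtype(arr.dtype, np.integer):
        return 16 if arr.max(initial=0) > 255 else 8
    raise ValueError(f"unsupported image dtype {arr.dtype}")


def _read_array(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def read_image(path: str | Path, px_per_um: float | None = None) -> Image2D:
    """Read a TIFF/PNG grayscale image losslessly.

    Bit depth is inferred from the stored sample format; ``px_per_um`` comes
    from the caller/config when the file metadata does not carry it.
    """
    arr = _read_array(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # flat RGB(A) from PNG
        if not (arr[..., 0] == arr[..., 1]).all():
            raise ValueError(f"{path}: color images are not supported")
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected 2 spatial dimensions, got shape {arr.shape}")
    return Image2D(arr, bit_depth=_infer_bit_depth(arr), px_per_um=px_per_um, id=Path(path).stem)


def write_image(image: Image2D, path: str | Path) -> None:
    """Write losslessly: 8-bit as uint8, 12/16-bit as uint16 TIFF/PNG."""
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    arr = image.pixels.astype(dtype)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_mask(path: str | Path, annotator_id: str = "") -> LabelMask:
    """Read a label or binary mask image.

    Binary inputs are component-labeled with 8-connectivity.  Instance
    inputs are trusted but re-checked: a label spread over several
    8-connected components is split with a warning.
    """
    arr = _read_array(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D mask, got shape {arr.shape}")
    if arr.dtype == bool:
        return connected_components(arr, annotator_id=annotator_id or Path(path).stem)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: non-integer pixel values in mask")
    aid = annotator_id or Path(path).stem
    uniq = np.unique(arr)
    if len(uniq) <= 2 and arr.max(initial=0) <= 1:
        return connected_components(arr > 0, annotator_id=aid)
    mask = LabelMask(arr.astype(np.int32), annotator_id=aid)
    return _check_connectivity(mask)


def _check_connectivity(mask: LabelMask) -> LabelMask:
    """Split labels that are not single 8-connected components."""
    out = np.zeros_like(mask.labels, dtype=np.int32)
    nxt = 1
    split = False
    for k in mask.ids:
        comp, n = ndimage.label(mask.labels == k, structure=STRUCTURE_8)
        if n > 1:
            split = True
        for c in range(1, n + 1):
            out[comp == c] = nxt
            nxt += 1
    if split:
        warnings.warn(
            f"mask {mask.annotator_id!r}: labels spanning several 8-connected "
            "components were split",
            stacklevel=2,
        )
        return LabelMask(out, annotator_id=mask.annotator_id)
    return relabel(mask)


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Store integer labels losslessly as 16-bit single-channel TIFF/PNG."""
    if mask.n_objects > 65535:
        raise ValueError("more than 65535 objects cannot be stored in 16-bit")
    arr = mask.labels.astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def connected_components(mask: np.ndarray, annotator_id: str = "") -> LabelMask:
    """Label maximal 8-connected foreground components 1..K."""
    mask = np.asarray(mask) > 0
    labels, _ = ndimage.label(mask, structure=STRUCTURE_8)
    return LabelMask(labels.astype(np.int32), annotator_id=annotator_id)


def relabel(mask: LabelMask) -> LabelMask:
    """Relabel object ids to consecutive 1..K (row-major first-appearance order)."""
    ids = np.unique(mask.labels)
    ids = ids[ids > 0]
    lut = np.zeros(int(ids.max(initial=0)) + 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1)
    return replace(mask, labels=lut[mask.labels])


def filter_min_size(mask: LabelMask, min_px: int) -> LabelMask:
    """Remove objects smaller than ``min_px`` pixels (area >= min_px survives).

    The minimum is derived from the smallest object a human expert annotated
    in a dataset, so an object exactly at the minimum is kept.
    """
    if min_px < 1:
        raise ValueError("min_px must be >= 1")
    if mask.n_objects == 0:
        return replace(mask, labels=mask.labels.copy())
    areas = np.bincount(mask.labels.ravel())
    kill = np.flatnonzero(areas < min_px)
    out = mask.labels.copy()
    if len(kill):
        out[np.isin(mask.labels, kill[kill > 0])] = 0
    return relabel(replace(mask, labels=out))


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a (Z, H, W) stack to 2-D."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a (Z, H, W) stack")
    return stack.max(axis=0)
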