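"""Image containers and the shared pixel-level substrate of all symptom pipelines.

The five symptom quantification pipelines (chlorosis, necrosis, deformation,
white spots, mosaic) all operate on a common vocabulary of objects:

* :class:`RgbImage` -- an H x W raster with integer red/green/blue channels at
  a declared working bit depth (8-bit for standard file formats, 10-bit to
  work on a 0-1023 grey scale).
* :class:`GrayImage` -- a single-channel, real-valued raster with a declared
  value range (e.g. the yellow component, or a contrast-stretched blue
  channel).
* :class:`BinaryMask` -- a boolean raster produced by thresholding.

This module also provides the shared operations: colour-component extraction,
the yellow component (``0.5*R + 0.5*G``) used for chlorosis, affine contrast
stretching, fixed-threshold binarization, connected-component labelling, and
the intensity-weighted centroid.

Axis convention (important)
---------------------------
Pixels are addressed 0-based, row-major, ``(i, j) = (row, column)``.  The
centroid coordinate ``cx`` is weighted by the ROW index ``i`` and is therefore
the row coordinate; ``cy`` is the COLUMN coordinate.  This matches the
definition of the weighted centroid used to split a leaf into quadrants, and
deliberately does *not* follow the screen-graphics habit of x = horizontal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "RgbImage",
    "GrayImage",
    "BinaryMask",
    "Centroid",
    "LabelledComponents",
    "LeafQuantError",
    "LeafNotFoundError",
    "compute_yellow",
    "extract_channel",
    "contrast_stretch",
    "binarize",
    "connected_components",
    "weighted_centroid",
    "read_rgb",
    "write_rgb",
    "write_gray",
    "write_mask",
]


class LeafQuantError(Exception):
    """Base class for all errors raised by this package."""


class LeafNotFoundError(LeafQuantError):
    """Raised when a pipeline cannot segment any leaf from the frame."""


@dataclass(frozen=True)
class RgbImage:
    """Three-channel integer raster at a declared bit depth (8 or 10).

    Channel values live in ``[0, max_value]`` with ``max_value = 2**bit_depth - 1``.
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    bit_depth: int = 8

    def __post_init__(self):
        if self.bit_depth not in (8, 10):
            raise ValueError(f"bit_depth must be 8 or 10, got {self.bit_depth}")
        r, g, b = self.red, self.green, self.blue
        if not (r.shape == g.shape == b.shape) or r.ndim != 2:
            raise ValueError("red/green/blue must be 2-D rasters of equal shape")
        for name, ch in (("red", r), ("green", g), ("blue", b)):
            if ch.min(initial=0) < 0 or ch.max(initial=0) > self.max_value:
                raise ValueError(f"{name} channel out of [0, {self.max_value}]")

    @property
    def height(self) -> int:
        return self.red.shape[0]

    @property
    def width(self) -> int:
        return self.red.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @classmethod
    def from_array(cls, arr: np.ndarray, bit_depth: int = 8) -> "RgbImage":
        """Build from an ``(H, W, 3)`` array."""
        if arr.ndim != 3 or arr.shape[2] < 3:
            raise ValueError("expected an (H, W, 3) array")
        a = np.asarray(arr)
        return cls(a[..., 0].copy(), a[..., 1].copy(), a[..., 2].copy(), bit_depth)

    def to_array(self) -> np.ndarray:
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        return np.stack([self.red, self.green, self.blue], axis=-1).astype(dtype)


@dataclass(frozen=True)
class GrayImage:
    """Single-channel real-valued raster with a declared ``value_range``."""

    values: np.ndarray
    value_range: tuple[float, float]

    def __post_init__(self):
        if self.values.ndim != 2 or 0 in self.values.shape:
            raise ValueError("values must be a non-empty 2-D raster")
        lo, hi = self.value_range
        if lo > hi:
            raise ValueError("value_range lower bound exceeds upper bound")
        v = self.values
        if v.min() < lo - 1e-9 or v.max() > hi + 1e-9:
            raise ValueError(
                f"values [{v.min()}, {v.max()}] outside declared range [{lo}, {hi}]"
            )

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BinaryMask:
    """Boolean raster; output of binarization, input to morphology/labelling."""

    values: np.ndarray

    def __post_init__(self):
        if self.values.dtype != bool or self.values.ndim != 2:
            raise ValueError("mask values must be a 2-D boolean raster")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())

    def complement(self) -> "BinaryMask":
        return BinaryMask(~self.values)


@dataclass(frozen=True)
class Centroid:
    """Intensity-weighted centre of mass; ``cx`` is the ROW coordinate."""

    cx: float
    cy: float


@dataclass(frozen=True)
class LabelledComponents:
    """Connected-component labelling of a binary mask.

    ``labels`` holds 0 for background and ``k >= 1`` per component;
    ``sizes[k-1]`` is the pixel count of component ``k``; ``border_touching[k-1]``
    flags components with at least one pixel on the frame border.
    """

    labels: np.ndarray
    sizes: np.ndarray
    border_touching: np.ndarray
    connectivity: int = 8

    @property
    def n_components(self) -> int:
        return len(self.sizes)


# ---------------------------------------------------------------------------
# Colour-component math


def compute_yellow(img: RgbImage) -> GrayImage:
    """Yellow component: equal-weight average of red and green, ``0.5*R + 0.5*G``.

    Chlorosis is a yellowing of green tissue, so yellow intensity tracks the
    symptom directly.  Kept real-valued (the average of two integers is
    generally a half-integer); quantization happens only on export.
    """
    y = 0.5 * img.red.astype(np.float64) + 0.5 * img.green.astype(np.float64)
    return GrayImage(y, (0.0, float(img.max_value)))


def extract_channel(img: RgbImage, channel: str) -> GrayImage:
    """Return one colour channel unchanged as a :class:`GrayImage`.

    The pipelines use the green channel for necrosis (best lesion contrast)
    and the blue channel for leaf-area segmentation (least sensitive to
    chlorosis and spots).
    """
    try:
        ch = {"red": img.red, "green": img.green, "blue": img.blue}[channel]
    except KeyError:
        raise ValueError(f"unknown channel {channel!r}; expected red/green/blue")
    return GrayImage(ch.astype(np.float64), (0.0, float(img.max_value)))


def contrast_stretch(img: GrayImage, out_lo: float, out_hi: float) -> GrayImage:
    """Affinely map ``[min(img), max(img)]`` onto ``[out_lo, out_hi]``.

    Monotone: the order of pixel values is preserved.  A constant image has no
    contrast to stretch; it is returned at the midpoint of the output range
    with a warning.
    """
    v = img.values
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        warnings.warn("contrast_stretch: constant image, returning midpoint", stacklevel=2)
        mid = 0.5 * (out_lo + out_hi)
        return GrayImage(np.full_like(v, mid, dtype=np.float64), (out_lo, out_hi))
    out = (v.astype(np.float64) - vmin) * ((out_hi - out_lo) / (vmax - vmin)) + out_lo
    # guard against rounding overshoot at the extremes
    out = np.clip(out, min(out_lo, out_hi), max(out_lo, out_hi))
    return GrayImage(out, (out_lo, out_hi))


def binarize(img: GrayImage, threshold: float, polarity: str = "above") -> BinaryMask:
    """Fixed-threshold binarization with strict comparison.

    ``polarity="above"`` keeps pixels ``> threshold`` (bright objects: white
    panel, white spots); ``"below"`` keeps pixels ``< threshold`` (dark
    objects: leaf tissue against the panel, necrotic lesions).  Pixels equal
    to the threshold are excluded either way.
    """
    if polarity == "above":
        return BinaryMask(img.values > threshold)
    if polarity == "below":
        return BinaryMask(img.values < threshold)
    raise ValueError(f"polarity must be 'above' or 'below', got {polarity!r}")


_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
_STRUCT_8 = np.ones((3, 3), bool)


def connected_components(mask: BinaryMask, connectivity: int = 8) -> LabelledComponents:
    """Label connected foreground regions under 4- or 8-adjacency.

    Backed by ``scipy.ndimage.label``; sizes and border-touching flags are
    reported per component.  The sum of sizes always equals the number of true
    pixels.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCT_4 if connectivity == 4 else _STRUCT_8
    labels, n = ndimage.label(mask.values, structure=structure)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    border = np.zeros(n, dtype=bool)
    if n:
        edge_labels = np.unique(
            np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
        )
        edge_labels = edge_labels[edge_labels > 0]
        border[edge_labels - 1] = True
    return LabelledComponents(labels, sizes, border, connectivity)


def weighted_centroid(img: GrayImage, mask: BinaryMask | None = None) -> Centroid:
    """Intensity-weighted centre of mass of a grayscale image.

    ``cx = sum(i * v) / sum(v)`` over rows ``i``; ``cy`` likewise over columns.
    With ``mask`` given, only pixels inside the mask contribute (the masked
    variant used when the background panel should not pull the centroid).
    """
    v = img.values.astype(np.float64)
    if mask is not None:
        if mask.shape != img.shape:
            raise ValueError("mask shape does not match image")
        v = np.where(mask.values, v, 0.0)
    total = v.sum()
    if total <= 0:
        raise LeafQuantError("weighted_centroid: zero total intensity")
    rows = np.arange(img.height, dtype=np.float64)
    cols = np.arange(img.width, dtype=np.float64)
    cx = float((v.sum(axis=1) * rows).sum() / total)
    cy = float((v.sum(axis=0) * cols).sum() / total)
    return Centroid(cx, cy)


# ---------------------------------------------------------------------------
# File I/O (PNG / TIFF / BMP / JPEG via imageio)


def read_rgb(path, bit_depth: int = 8) -> RgbImage:
    """Read an image file as an :class:`RgbImage` at the declared working depth.

    8-bit sources are used as-is at depth 8 or left-shifted to depth 10;
    16-bit sources (e.g. 16-bit TIFF) are right-shifted down to the declared
    depth.  Alpha channels and grayscale sources are handled by dropping /
    replicating channels.
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] > 3:
        arr = arr[..., :3]
    src_bits = 16 if arr.dtype.itemsize >= 2 else 8
    arr = arr.astype(np.int64)
    if src_bits > bit_depth:
        arr >>= src_bits - bit_depth
    elif src_bits < bit_depth:
        arr <<= bit_depth - src_bits
    return RgbImage.from_array(arr, bit_depth=bit_depth)


def write_rgb(path, img: RgbImage) -> None:
    import imageio.v3 as iio

    arr = img.to_array()
    if img.bit_depth == 10:
        arr = (arr.astype(np.uint16) << 6)  # left-justify into 16-bit PNG/TIFF
    iio.imwrite(path, arr)


def write_gray(path, img: GrayImage) -> None:
    """Quantize a grayscale image into 8-bit for export."""
    import imageio.v3 as iio

    lo, hi = img.value_range
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    arr = np.clip((img.values - lo) * scale, 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def write_mask(path, mask: BinaryMask) -> None:
    """Export a binary mask as a 0/255 PNG."""
    import imageio.v3 as iio

    iio.imwrite(path, mask.values.astype(np.uint8) * 255)
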