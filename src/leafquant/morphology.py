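"""Binary and grayscale mathematical morphology.

Erosion, dilation, opening, closing, top-hat and bottom-hat with an explicit
structuring element ``B``.  These operators are the workhorses of the necrosis
pipeline (grayscale opening as a pre-threshold "median-like" denoiser) and the
mosaic pipeline (top-hat/bottom-hat venation enhancement).

Definitions
-----------
For a binary image ``A`` and structuring element ``B`` with reflection ``C``:

* erosion   ``A (-) B``: the set of positions ``z`` where ``B`` translated to
  ``z`` is entirely contained in ``A``;
* dilation  ``A (+) B``: the positions where ``C`` translated to ``z`` overlaps
  ``A`` in at least one cell;
* opening   ``gamma_B(A) = (A (-) B) (+) B``;
* closing   ``phi_B(A)   = (A (+) B) (-) B``;
* top-hat    ``A - gamma_B(A)``  (small bright structures);
* bottom-hat ``phi_B(A) - A``    (small dark structures).

Grayscale erosion/dilation replace containment/overlap by neighbourhood
min/max.

Border policy
-------------
Binary erosion and dilation treat everything outside the frame as background
(the literal set definitions on the finite pixel set) -- so an eroded mask can
never hug the frame border unless the element fits.  Binary opening and
closing are evaluated on an enlarged canvas and cropped, which makes them
equal to the infinite-plane definitions restricted to the frame; this is what
preserves the classical algebraic properties (opening anti-extensive and
idempotent, closing extensive and idempotent) all the way to the border.
Grayscale operators take the min/max over the part of the neighbourhood that
lies inside the frame (equivalently: erosion padded with the range maximum,
dilation with the range minimum), which keeps a constant image constant and
both hat transforms zero on it.

The exact pad value is exposed as an argument so callers (and property tests)
can state complement-duality with the mathematically matching convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_core import BinaryMask, GrayImage

__all__ = [
    "StructuringElement",
    "erode",
    "dilate",
    "open_",
    "close",
    "top_hat",
    "bottom_hat",
]


@dataclass(frozen=True)
class StructuringElement:
    """A small boolean neighbourhood pattern ``B`` with an origin.

    ``reflect()`` returns the point reflection ``C`` of the pattern through
    its origin, used by dilation; reflecting twice gives back the original.
    """

    pattern: np.ndarray
    origin: tuple[int, int]

    def __post_init__(self):
        p = self.pattern
        if p.dtype != bool or p.ndim != 2:
            raise ValueError("pattern must be a 2-D boolean array")
        if not p.any():
            raise ValueError("structuring element must have at least one true cell")
        r, c = self.origin
        if not (0 <= r < p.shape[0] and 0 <= c < p.shape[1]):
            raise ValueError("origin outside pattern bounds")

    @classmethod
    def box(cls, n: int) -> "StructuringElement":
        """n x n square, origin at the centre."""
        if n < 1:
            raise ValueError("box size must be >= 1")
        return cls(np.ones((n, n), bool), (n // 2, n // 2))

    @classmethod
    def disk(cls, radius: int) -> "StructuringElement":
        """Digital disk of the given radius (side ``2r + 1``)."""
        if radius < 0:
            raise ValueError("disk radius must be >= 0")
        n = 2 * radius + 1
        yy, xx = np.mgrid[:n, :n]
        pat = (yy - radius) ** 2 + (xx - radius) ** 2 <= radius**2
        return cls(pat, (radius, radius))

    @classmethod
    def cross(cls, n: int) -> "StructuringElement":
        """Plus-shaped element spanning an n x n box."""
        if n < 1 or n % 2 == 0:
            raise ValueError("cross size must be odd and >= 1")
        pat = np.zeros((n, n), bool)
        pat[n // 2, :] = True
        pat[:, n // 2] = True
        return cls(pat, (n // 2, n // 2))

    @classmethod
    def from_text(cls, text: str) -> "StructuringElement":
        """Parse a rows-of-0/1 grid; the origin cell is marked ``2`` (or the
        geometric centre if no ``2`` appears)."""
        rows = [ln.split() if " " in ln else list(ln) for ln in text.strip().splitlines()]
        grid = np.array([[int(c) for c in row] for row in rows])
        origin_cells = np.argwhere(grid == 2)
        if len(origin_cells) > 1:
            raise ValueError("more than one origin marker in structuring element text")
        origin = (
            tuple(origin_cells[0])
            if len(origin_cells)
            else (grid.shape[0] // 2, grid.shape[1] // 2)
        )
        return cls(grid > 0, (int(origin[0]), int(origin[1])))

    def to_text(self) -> str:
        grid = self.pattern.astype(int)
        r, c = self.origin
        grid = grid.copy()
        if grid[r, c]:
            grid[r, c] = 2
        return "\n".join("".join(str(x) for x in row) for row in grid)

    def reflect(self) -> "StructuringElement":
        p = self.pattern[::-1, ::-1].copy()
        r, c = self.origin
        return StructuringElement(
            p, (p.shape[0] - 1 - r, p.shape[1] - 1 - c)
        )

    def offsets(self) -> np.ndarray:
        """(dr, dc) of true cells relative to the origin."""
        rc = np.argwhere(self.pattern)
        return rc - np.array(self.origin)


# ---------------------------------------------------------------------------
# Array-level kernels.  Each reduces over shifted copies of a padded array --
# one pass per true cell of the element, which is fast for the small elements
# used here (<= 9 x 9).


def _reduce_shifted(arr, offsets, pad_value, op):
    h, w = arr.shape
    m = int(np.abs(offsets).max(initial=0))
    padded = np.pad(arr, m, mode="constant", constant_values=pad_value)
    out = None
    for dr, dc in offsets:
        window = padded[m + dr : m + dr + h, m + dc : m + dc + w]
        out = window.copy() if out is None else op(out, window)
    return out


def _binary_erode(arr: np.ndarray, se: StructuringElement, pad: bool = False) -> np.ndarray:
    return _reduce_shifted(arr, se.offsets(), pad, np.logical_and)


def _binary_dilate(arr: np.ndarray, se: StructuringElement, pad: bool = False) -> np.ndarray:
    return _reduce_shifted(arr, se.reflect().offsets(), pad, np.logical_or)


def _gray_erode(arr: np.ndarray, se: StructuringElement) -> np.ndarray:
    return _reduce_shifted(arr.astype(np.float64), se.offsets(), np.inf, np.minimum)


def _gray_dilate(arr: np.ndarray, se: StructuringElement) -> np.ndarray:
    return _reduce_shifted(
        arr.astype(np.float64), se.reflect().offsets(), -np.inf, np.maximum
    )


def _se_margin(se: StructuringElement) -> int:
    return int(np.abs(se.offsets()).max(initial=0)) + 1


# ---------------------------------------------------------------------------
# Typed operators


def erode(img, se: StructuringElement, *, pad: bool = False):
    """Morphological erosion.

    Binary: a pixel survives iff ``B`` translated there fits entirely inside
    the foreground (``pad`` gives the assumed value outside the frame; the
    default ``False`` is the strict set definition).  Grayscale: neighbourhood
    minimum over the in-frame part of ``B``.
    """
    if isinstance(img, BinaryMask):
        return BinaryMask(_binary_erode(img.values, se, pad))
    if isinstance(img, GrayImage):
        return GrayImage(_gray_erode(img.values, se), img.value_range)
    raise TypeError("erode expects a BinaryMask or GrayImage")


def dilate(img, se: StructuringElement, *, pad: bool = False):
    """Morphological dilation: reflected-element overlap (binary) / neighbourhood
    maximum (grayscale)."""
    if isinstance(img, BinaryMask):
        return BinaryMask(_binary_dilate(img.values, se, pad))
    if isinstance(img, GrayImage):
        return GrayImage(_gray_dilate(img.values, se), img.value_range)
    raise TypeError("dilate expects a BinaryMask or GrayImage")


def open_(img, se: StructuringElement):
    """Opening: erosion then dilation.  Removes bright/foreground structures
    smaller than the element; anti-extensive and idempotent."""
    if isinstance(img, BinaryMask):
        m = _se_margin(se)
        a = np.pad(img.values, m, mode="constant", constant_values=False)
        out = _binary_dilate(_binary_erode(a, se), se)
        return BinaryMask(out[m:-m, m:-m])
    if isinstance(img, GrayImage):
        return GrayImage(_gray_dilate(_gray_erode(img.values, se), se), img.value_range)
    raise TypeError("open_ expects a BinaryMask or GrayImage")


def close(img, se: StructuringElement):
    """Closing: dilation then erosion.  Fills dark/background structures
    smaller than the element; extensive and idempotent.

    The binary form runs on an enlarged canvas so that the result equals the
    infinite-plane closing restricted to the frame (otherwise border pixels
    could be lost, breaking extensivity).
    """
    if isinstance(img, BinaryMask):
        m = _se_margin(se)
        a = np.pad(img.values, m, mode="constant", constant_values=False)
        out = _binary_erode(_binary_dilate(a, se), se)
        return BinaryMask(out[m:-m, m:-m])
    if isinstance(img, GrayImage):
        return GrayImage(_gray_erode(_gray_dilate(img.values, se), se), img.value_range)
    raise TypeError("close expects a BinaryMask or GrayImage")


def top_hat(img: GrayImage, se: StructuringElement) -> GrayImage:
    """White top-hat: image minus its opening; non-negative, responds to
    bright structures thinner than the element (e.g. back-lit venation)."""
    if not isinstance(img, GrayImage):
        raise TypeError("top_hat expects a GrayImage")
    opened = _gray_dilate(_gray_erode(img.values, se), se)
    out = img.values - opened
    lo, hi = img.value_range
    return GrayImage(out, (0.0, hi - lo))


def bottom_hat(img: GrayImage, se: StructuringElement) -> GrayImage:
    """Black bottom-hat: closing minus image; non-negative, responds to dark
    structures thinner than the element."""
    if not isinstance(img, GrayImage):
        raise TypeError("bottom_hat expects a GrayImage")
    closed = _gray_erode(_gray_dilate(img.values, se), se)
    out = closed - img.values
    lo, hi = img.value_range
    return GrayImage(out, (0.0, hi - lo))
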