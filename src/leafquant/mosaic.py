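"""Mosaic (vein-clearing) density on back-lit leaf images.

Vein-clearing mosaic makes leaf venation abnormally light; under high-intensity
back-light the venation network transmits more light than the lamina and can
be quantified.  Pipeline on the blue channel of a back-lit frame:

1. **Contrast stretch** of the blue channel onto the full working grey range
   (0..255 at 8-bit depth, 0..1023 at 10-bit).
2. **Top-hat / bottom-hat enhancement** with a structuring element wider than
   a vein: the default combination is the classical
   ``enhanced = stretched + top_hat - bottom_hat`` (clamped to the range),
   which brightens thin bright structure and darkens thin dark structure; a
   literal "sequential replacement" mode is kept as an option.
3. **Canny edge detection** (Gaussian smoothing, Sobel gradient, non-maximum
   suppression, double-threshold hysteresis).  The low/high thresholds are
   specified as fractions of the maximum gradient magnitude, which makes the
   result invariant to global brightness/contrast offsets that the stretch
   has not already removed.
4. **Area ratio**: the edge pixels inside the leaf silhouette are counted as
   ``A_map`` and reported relative to the total leaf area ``A_TL``:

       A_mosaic = 100 * A_map / A_TL    [percent]

Leaf-outline edges are included in ``A_map`` (no attempt is made to subtract
them); for a venation-free leaf they are the only contribution and amount to
roughly perimeter/area, well under 2% for frame-filling leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging_core import (
    BinaryMask,
    GrayImage,
    RgbImage,
    contrast_stretch,
    extract_channel,
)
from .morphology import StructuringElement, bottom_hat, top_hat
from .necrosis import segment_leaf

__all__ = ["MosaicResult", "enhance_venation", "canny", "quantify_mosaic"]


@dataclass(frozen=True)
class MosaicResult:
    a_map: int  #: venation-edge pixels inside the leaf
    a_tl: int  #: total leaf pixels
    a_mosaic: float  #: percentage of leaf area covered by mosaic edges
    params: dict = field(default_factory=dict)


def enhance_venation(
    img: RgbImage,
    se: StructuringElement | None = None,
    stretch_hi: float | None = None,
    combine: str = "additive",
) -> GrayImage:
    """Contrast-stretch the blue channel and enhance thin venation structure.

    ``se`` defaults to a disk of radius 4 (9 x 9), wider than a vein so the
    top-hat responds to the full vein cross-section.  ``combine`` selects how
    the two hat transforms act on the stretched image ``s``:

    * ``"additive"`` (default): ``clamp(s + Thw(s) - Thb(s))``;
    * ``"sequential"``: ``s`` is replaced by its top-hat, then the bottom-hat
      of that intermediate is subtracted (a literal reading of applying the
      two transforms one after the other).

    A constant blue channel carries no venation information; it is passed
    through (both hats are zero) behind the constant-image stretch warning.
    """
    if se is None:
        se = StructuringElement.disk(4)
    if stretch_hi is None:
        stretch_hi = float(img.max_value)
    blue = extract_channel(img, "blue")
    stretched = contrast_stretch(blue, 0.0, stretch_hi)
    thw = top_hat(stretched, se)
    if combine == "additive":
        thb = bottom_hat(stretched, se)
        out = stretched.values + thw.values - thb.values
    elif combine == "sequential":
        inter = GrayImage(np.clip(thw.values, 0.0, stretch_hi), (0.0, stretch_hi))
        out = inter.values - bottom_hat(inter, se).values
    else:
        raise ValueError(f"unknown hat combination {combine!r}")
    return GrayImage(np.clip(out, 0.0, stretch_hi), (0.0, stretch_hi))


def canny(
    values: np.ndarray,
    sigma: float = 1.4,
    lo_frac: float = 0.1,
    hi_frac: float = 0.25,
) -> np.ndarray:
    """Canny edge detector with thresholds as fractions of the peak gradient.

    Gaussian smoothing at ``sigma``, Sobel gradients, 4-sector non-maximum
    suppression (ties broken toward one side so straight edges come out one
    pixel thin), then hysteresis: keep weak-edge pixels (>= lo) only in
    8-connected components that contain a strong pixel (>= hi).
    """
    v = np.asarray(values, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(v, sigma, mode="nearest")
    gr = ndimage.sobel(smoothed, axis=0, mode="nearest")
    gc = ndimage.sobel(smoothed, axis=1, mode="nearest")
    mag = np.hypot(gr, gc)
    gmax = mag.max()
    if gmax == 0:
        return np.zeros_like(v, dtype=bool)

    # quantize gradient direction into 4 sectors and take the two neighbours
    # along the gradient
    angle = np.mod(np.arctan2(gr, gc), np.pi)  # [0, pi)
    sector = ((angle + np.pi / 8) // (np.pi / 4)).astype(int) % 4
    # sector 0: gradient ~ horizontal -> neighbours left/right (dc)
    # sector 1: ~ 45 deg, 2: vertical (dr), 3: ~ 135 deg
    offs = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}
    padded = np.pad(mag, 1, mode="constant")
    nms = np.zeros_like(mag, dtype=bool)
    h, w = mag.shape
    for s, (dr, dc) in offs.items():
        fwd = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        bwd = padded[1 - dr : 1 - dr + h, 1 - dc : 1 - dc + w]
        keep = (mag >= fwd) & (mag > bwd)
        nms |= keep & (sector == s)
    mag_nms = np.where(nms, mag, 0.0)

    weak = mag_nms >= lo_frac * gmax
    strong = mag_nms >= hi_frac * gmax
    labels, n = ndimage.label(weak, structure=np.ones((3, 3), bool))
    if n == 0:
        return np.zeros_like(weak)
    has_strong = np.zeros(n + 1, dtype=bool)
    has_strong[np.unique(labels[strong])] = True
    has_strong[0] = False
    return has_strong[labels]


def quantify_mosaic(
    img: RgbImage,
    se: StructuringElement | None = None,
    sigma: float = 1.4,
    edge_lo: float = 0.1,
    edge_hi: float = 0.25,
    t_leaf: float | None = None,
    stretch_hi: float | None = None,
    combine: str = "additive",
) -> MosaicResult:
    """Percentage of leaf area covered by venation (mosaic) edges."""
    if se is None:
        se = StructuringElement.disk(4)
    leaf = segment_leaf(img, t_leaf)
    a_tl = leaf.count()
    enhanced = enhance_venation(img, se, stretch_hi, combine)
    edges = canny(enhanced.values, sigma, edge_lo, edge_hi)
    a_map = int((edges & leaf.values).sum())
    return MosaicResult(
        a_map,
        a_tl,
        100.0 * a_map / a_tl,
        params={
            "se": se.to_text(),
            "sigma": sigma,
            "edge_lo": edge_lo,
            "edge_hi": edge_hi,
            "combine": combine,
        },
    )
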