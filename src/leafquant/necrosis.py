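"""Necrotic-area quantification.

Necrosis shows as brown/black (dark) lesions.  The pipeline uses two colour
channels for two different jobs:

* the **green** channel segments the lesions -- it gives the best contrast
  between necrotic and healthy tissue, and crucially stays high on chlorotic
  (yellowed) tissue, so yellowing does not masquerade as necrosis;
* the **blue** channel segments the whole leaf from the bright panel
  background -- it is the channel least affected by chlorosis and spots.

Steps: grayscale opening of the green channel with a small structuring
element (denoises bright speckle before thresholding), dark-object
binarization below ``t_necro`` restricted to the leaf silhouette, then

    A_n = 100 * A_np / A_T    [percent]

with ``A_np`` the necrotic pixel count and ``A_T`` the total leaf pixel count
from the blue-channel silhouette (largest connected dark component).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_core import (
    BinaryMask,
    LeafNotFoundError,
    RgbImage,
    binarize,
    connected_components,
    extract_channel,
)
from .morphology import StructuringElement, open_

__all__ = ["NecrosisResult", "segment_leaf", "quantify_necrosis"]

#: default thresholds as fractions of the channel maximum
T_LEAF_FRAC = 0.80
T_NECRO_FRAC = 0.35


@dataclass(frozen=True)
class NecrosisResult:
    a_np: int
    a_t: int
    a_n: float  #: percentage of leaf area that is necrotic
    params: dict = field(default_factory=dict)


def segment_leaf(
    img: RgbImage, t_leaf: float | None = None, connectivity: int = 8
) -> BinaryMask:
    """Segment the leaf silhouette from the blue channel.

    The leaf is darker than the white/LED panel in blue, so pixels below
    ``t_leaf`` (default ``0.80 * max_value``) are leaf candidates; the largest
    connected component is kept, discarding stray dark debris.
    """
    if t_leaf is None:
        t_leaf = T_LEAF_FRAC * img.max_value
    blue = extract_channel(img, "blue")
    dark = binarize(blue, t_leaf, "below")
    comps = connected_components(dark, connectivity)
    if comps.n_components == 0:
        raise LeafNotFoundError("no leaf found: blue channel has no dark component")
    biggest = int(np.argmax(comps.sizes)) + 1
    return BinaryMask(comps.labels == biggest)


def quantify_necrosis(
    img: RgbImage,
    t_necro: float | None = None,
    t_leaf: float | None = None,
    se: StructuringElement | None = None,
    connectivity: int = 8,
) -> NecrosisResult:
    """Percentage of the leaf silhouette covered by necrotic lesions.

    The opening is applied to the green channel *before* binarization
    (grayscale-first), and necrotic pixels are counted inside the leaf mask
    only, so the background cannot contribute.
    """
    if t_necro is None:
        t_necro = T_NECRO_FRAC * img.max_value
    if se is None:
        se = StructuringElement.box(3)
    leaf = segment_leaf(img, t_leaf, connectivity)
    a_t = leaf.count()
    green = extract_channel(img, "green")
    smoothed = open_(green, se)
    dark = binarize(smoothed, t_necro, "below")
    necrotic = dark.values & leaf.values
    a_np = int(necrotic.sum())
    a_n = 100.0 * a_np / a_t
    return NecrosisResult(
        a_np,
        a_t,
        a_n,
        params={
            "t_necro": float(t_necro),
            "t_leaf": float(t_leaf if t_leaf is not None else T_LEAF_FRAC * img.max_value),
            "se": se.to_text(),
            "connectivity": connectivity,
        },
    )
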