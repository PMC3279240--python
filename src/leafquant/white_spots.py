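"""White-spot area quantification by three-way pixel accounting.

White spots are bright lesions (impaired chlorophyll biosynthesis, e.g. zinc
deficiency).  In the blue channel both the panel background and the spots are
bright while healthy/chlorotic/necrotic tissue is dark, so one threshold
splits the frame into bright and dark pixels; connected-component bookkeeping
then separates the three classes:

* ``A_BG``  -- background: the bright components touching the frame border
  (a spot strictly inside the leaf can never reach the border, so this is the
  parameter-free way to keep interior spots out of the background count);
* ``A_TL``  -- leaf without spots: the largest dark component;
* ``A_ws = A_ZS - A_BG - A_TL`` -- everything else, i.e. the white spots
  (plus any stray dark noise outside the leaf -- a documented artifact of the
  accounting identity, mitigated by the optional ``denoise_se``);

with ``A_ZS`` the total frame size.  The reported percentage is relative to
the whole leaf (tissue plus spots):

    A_pws = 100 * A_ws / (A_TL + A_ws)

The accounting identity ``A_ZS = A_BG + A_TL + A_ws`` holds exactly by
construction and ``A_ws`` can never be negative (the two counted classes are
disjoint subsets of the frame).
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
from .morphology import StructuringElement, close

__all__ = ["WhiteSpotsResult", "quantify_white_spots"]

T_SPOT_FRAC = 0.80


@dataclass(frozen=True)
class WhiteSpotsResult:
    a_zs: int  #: total frame pixels
    a_bg: int  #: bright border-touching (panel) pixels
    a_tl: int  #: largest dark component (leaf without spots)
    a_ws: int  #: white-spot pixels by the accounting identity
    a_pws: float  #: percentage of leaf area occupied by white spots
    params: dict = field(default_factory=dict)


def quantify_white_spots(
    img: RgbImage,
    t: float | None = None,
    connectivity: int = 8,
    denoise_se: StructuringElement | None = None,
) -> WhiteSpotsResult:
    """Percentage of leaf area occupied by white spots.

    ``t`` is the bright threshold on the blue channel (default
    ``0.80 * max_value``; fixed but user-adjustable to the light conditions).
    ``denoise_se`` optionally closes the bright mask first, absorbing small
    dark debris outside the leaf that would otherwise be booked as spots.
    """
    if t is None:
        t = T_SPOT_FRAC * img.max_value
    blue = extract_channel(img, "blue")
    bright = binarize(blue, t, "above")
    if denoise_se is not None:
        bright = close(bright, denoise_se)
    a_zs = img.height * img.width

    bright_comps = connected_components(bright, connectivity)
    a_bg = int(bright_comps.sizes[bright_comps.border_touching].sum())

    dark_comps = connected_components(bright.complement(), connectivity)
    if dark_comps.n_components == 0:
        raise LeafNotFoundError("no leaf found: frame is entirely background")
    a_tl = int(dark_comps.sizes.max())

    a_ws = a_zs - a_bg - a_tl
    a_pws = 100.0 * a_ws / (a_tl + a_ws)
    return WhiteSpotsResult(
        a_zs,
        a_bg,
        a_tl,
        a_ws,
        a_pws,
        params={"t": float(t), "connectivity": connectivity},
    )
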