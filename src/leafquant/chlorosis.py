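"""Chlorosis quantification: overall yellowing level and its localization.

Chlorosis (yellowing of normally green tissue) is quantified from the yellow
component ``0.5*R + 0.5*G``.  The image is split into four quadrants around
the intensity-weighted centroid of the yellow image; for each quadrant ``k``
the mean yellow value ``R_k`` over its ``L_k`` pixels is computed.  Two scalar
summaries follow:

* ``R_n = ||[R_1, R_2, R_3, R_4]||`` -- the modulus of the four quadrant means;
  measures how chlorotic the leaf is as a whole (a uniformly yellow leaf with
  yellow value ``v`` gives ``R_n = 2v``).
* ``R_diff = ||[R_1-R_2, R_1-R_3, R_1-R_4, R_2-R_3, R_2-R_4, R_3-R_4]||`` --
  the modulus of the six pairwise differences; near zero when yellowing is
  generalized, large when it is localized in some quadrants.

Both are invariant to relabelling the quadrants (they are vector moduli), so
the exact tie-break on the quadrant boundary is immaterial; boundary pixels go
to the >= side.

By default the quadrant means are taken over leaf pixels only (leaf mask from
blue-channel segmentation) so that the bright panel background does not swamp
the means; a whole-frame mode is available for the literal definition.  The
package reports the raw ``(R_n, R_diff)`` pair in native intensity units and
deliberately draws no localized/generalized classification cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imaging_core import (
    BinaryMask,
    Centroid,
    GrayImage,
    LeafQuantError,
    RgbImage,
    compute_yellow,
    weighted_centroid,
)
from .necrosis import segment_leaf

__all__ = ["ChlorosisResult", "partition_regions", "quantify_chlorosis"]

_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass(frozen=True)
class ChlorosisResult:
    """Quadrant yellow means and the two modulus summaries.

    ``region_means[k]`` is NaN for a quadrant with no (leaf) pixels; such
    quadrants are excluded from both moduli.
    """

    region_means: tuple[float, float, float, float]
    l_counts: tuple[int, int, int, int]
    rn: float
    rdiff: float
    centroid: Centroid

    def defined_regions(self) -> list[int]:
        return [k for k, m in enumerate(self.region_means) if not np.isnan(m)]


def partition_regions(
    img: GrayImage, c: Centroid, leaf_mask: BinaryMask | None = None
) -> list[np.ndarray]:
    """Split pixels into four quadrant masks around the centroid.

    Quadrant order: (top-left, top-right, bottom-left, bottom-right) by
    ``row < cx`` / ``col < cy``; boundary pixels join the >= side.  With a
    leaf mask, background pixels are excluded from every quadrant.
    """
    if not (0 <= c.cx < img.height and 0 <= c.cy < img.width):
        raise LeafQuantError(f"centroid {c} outside image frame")
    rows = np.arange(img.height)[:, None] < c.cx
    cols = np.arange(img.width)[None, :] < c.cy
    quads = [
        rows & cols,
        rows & ~cols,
        ~rows & cols,
        ~rows & ~cols,
    ]
    quads = [np.broadcast_to(q, img.shape).copy() for q in quads]
    if leaf_mask is not None:
        if leaf_mask.shape != img.shape:
            raise LeafQuantError("leaf mask shape does not match image")
        quads = [q & leaf_mask.values for q in quads]
    return quads


def quantify_chlorosis(
    img: RgbImage,
    leaf_mask: BinaryMask | None = None,
    *,
    masked: bool = True,
    centroid: Centroid | None = None,
    centroid_masked: bool = False,
    t_leaf: float | None = None,
) -> ChlorosisResult:
    """Quantify chlorosis level (``R_n``) and localization (``R_diff``).

    Parameters
    ----------
    leaf_mask:
        Restrict quadrant means to these pixels.  If None and ``masked`` is
        true, a leaf mask is segmented from the blue channel; if ``masked`` is
        false the whole frame is used (literal definition).
    centroid:
        Override the partitioning centroid.  By default it is the weighted
        centroid of the whole-frame yellow image; with ``centroid_masked`` it
        is restricted to the leaf mask.
    t_leaf:
        Blue-channel leaf threshold for auto-segmentation
        (default ``0.80 * max_value``).
    """
    yellow = compute_yellow(img)
    if masked and leaf_mask is None:
        leaf_mask = segment_leaf(img, t_leaf)
    if not masked:
        leaf_mask = None
    if centroid is None:
        centroid = weighted_centroid(yellow, leaf_mask if centroid_masked else None)
    quads = partition_regions(yellow, centroid, leaf_mask)
    means: list[float] = []
    counts: list[int] = []
    for k, q in enumerate(quads):
        n = int(q.sum())
        counts.append(n)
        if n == 0:
            warnings.warn(f"chlorosis: quadrant {k + 1} has no pixels; excluded", stacklevel=2)
            means.append(float("nan"))
        else:
            means.append(float(yellow.values[q].mean()))
    defined = [m for m in means if not np.isnan(m)]
    rn = float(np.sqrt(np.sum(np.square(defined)))) if defined else float("nan")
    diffs = [
        means[a] - means[b]
        for a, b in _PAIRS
        if not (np.isnan(means[a]) or np.isnan(means[b]))
    ]
    rdiff = float(np.sqrt(np.sum(np.square(diffs)))) if diffs else float("nan")
    return ChlorosisResult(tuple(means), tuple(counts), rn, rdiff, centroid)
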