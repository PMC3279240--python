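"""Independent brute-force oracles for the property/acceptance tests.

Everything here is written from the textbook definitions with explicit Python
loops, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected-component labelling by BFS flood fill."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and labels[i, j] == 0:
                current += 1
                queue = [(i, j)]
                labels[i, j] = current
                while queue:
                    r, c = queue.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = current
                            queue.append((rr, cc))
    return labels


def centroid_loops(values: np.ndarray) -> tuple[float, float]:
    """Double-loop intensity-weighted centroid."""
    num_r = num_c = den = 0.0
    h, w = values.shape
    for i in range(h):
        for j in range(w):
            v = float(values[i, j])
            num_r += i * v
            num_c += j * v
            den += v
    return num_r / den, num_c / den


def _se_offsets(pattern: np.ndarray, origin: tuple[int, int]):
    out = []
    for r in range(pattern.shape[0]):
        for c in range(pattern.shape[1]):
            if pattern[r, c]:
                out.append((r - origin[0], c - origin[1]))
    return out


def _reflect(pattern, origin):
    p = pattern[::-1, ::-1]
    return p, (p.shape[0] - 1 - origin[0], p.shape[1] - 1 - origin[1])


def binary_erode(mask, pattern, origin, pad=False):
    """Set-definition erosion: the element translated there must fit in the
    foreground; cells falling outside the frame take the pad value."""
    h, w = mask.shape
    out = np.zeros((h, w), bool)
    offs = _se_offsets(pattern, origin)
    for i in range(h):
        for j in range(w):
            ok = True
            for dr, dc in offs:
                r, c = i + dr, j + dc
                v = mask[r, c] if 0 <= r < h and 0 <= c < w else pad
                if not v:
                    ok = False
                    break
            out[i, j] = ok
    return out


def binary_dilate(mask, pattern, origin, pad=False):
    """Overlap-definition dilation with the reflected element."""
    rp, ro = _reflect(pattern, origin)
    h, w = mask.shape
    out = np.zeros((h, w), bool)
    offs = _se_offsets(rp, ro)
    for i in range(h):
        for j in range(w):
            hit = False
            for dr, dc in offs:
                r, c = i + dr, j + dc
                v = mask[r, c] if 0 <= r < h and 0 <= c < w else pad
                if v:
                    hit = True
                    break
            out[i, j] = hit
    return out


def binary_open(mask, pattern, origin):
    """Plane opening restricted to the frame (computed on an enlarged canvas)."""
    m = max(pattern.shape) + 1
    big = np.zeros((mask.shape[0] + 2 * m, mask.shape[1] + 2 * m), bool)
    big[m:-m, m:-m] = mask
    out = binary_dilate(binary_erode(big, pattern, origin), pattern, origin)
    return out[m:-m, m:-m]


def binary_close(mask, pattern, origin):
    m = max(pattern.shape) + 1
    big = np.zeros((mask.shape[0] + 2 * m, mask.shape[1] + 2 * m), bool)
    big[m:-m, m:-m] = mask
    out = binary_erode(binary_dilate(big, pattern, origin), pattern, origin)
    return out[m:-m, m:-m]


def gray_erode(values, pattern, origin):
    """Neighbourhood minimum over the in-frame part of the element."""
    h, w = values.shape
    out = np.empty((h, w), float)
    offs = _se_offsets(pattern, origin)
    for i in range(h):
        for j in range(w):
            best = np.inf
            for dr, dc in offs:
                r, c = i + dr, j + dc
                if 0 <= r < h and 0 <= c < w:
                    best = min(best, float(values[r, c]))
            out[i, j] = best
    return out


def gray_dilate(values, pattern, origin):
    rp, ro = _reflect(pattern, origin)
    h, w = values.shape
    out = np.empty((h, w), float)
    offs = _se_offsets(rp, ro)
    for i in range(h):
        for j in range(w):
            best = -np.inf
            for dr, dc in offs:
                r, c = i + dr, j + dc
                if 0 <= r < h and 0 <= c < w:
                    best = max(best, float(values[r, c]))
            out[i, j] = best
    return out


def gray_open(values, pattern, origin):
    return gray_dilate(gray_erode(values, pattern, origin), pattern, origin)


def gray_close(values, pattern, origin):
    return gray_erode(gray_dilate(values, pattern, origin), pattern, origin)


def gray_top_hat(values, pattern, origin):
    return np.asarray(values, float) - gray_open(values, pattern, origin)


def gray_bottom_hat(values, pattern, origin):
    return gray_close(values, pattern, origin) - np.asarray(values, float)


def random_se(rng):
    """A random structuring element up to 5x5 containing its origin."""
    h = int(rng.integers(1, 6))
    w = int(rng.integers(1, 6))
    pattern = rng.random((h, w)) < 0.6
    origin = (int(rng.integers(h)), int(rng.integers(w)))
    pattern[origin] = True  # keep the origin inside the support for sanity
    return pattern, origin
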