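"""Parametric synthetic diseased-leaf image generator with exact ground truth.

Real leaf photographs with known symptom severities are not available, so the
test and acceptance substrate is generated: a leaf silhouette on a bright
uniform panel, painted with controllable amounts of each symptom and an exact
per-pixel class raster.  The generator emulates the two imaging modes used
for leaf symptom capture:

* ``lighting="panel"``: leaf in front of an opaque white panel (chlorosis,
  necrosis, deformation, white spots);
* ``lighting="backlit"``: leaf against a bright LED panel, venation brighter
  than the lamina (mosaic / vein-clearing).

Silhouette model
----------------
A star-shaped polar curve around the frame centre,

    r(theta) = R * (1 + a * cos(k * theta) + rho * g(theta))

with a small ``k``-lobe modulation (leaf-like scallops) and, for deformation
studies, seeded band-limited radial noise ``g`` (harmonics 8..24, normalized
to unit peak) scaled by the relative ``boundary_roughness`` ``rho``.  The
analytic area and perimeter of the *unperturbed* curve (``rho = 0``) are
recorded in the ground truth, so rasterization error of area/perimeter
estimators can be measured against a closed-form reference.

Intensity bands
---------------
Each pixel class (background / tissue / chlorotic / necrotic / spot / vein)
is painted in a colour band; in every channel that a pipeline thresholds, the
bands on either side of the default threshold are separated by well over 10%
of the channel maximum even after the +/-3 grey-level pixel jitter, so
thresholding at the default levels recovers the class raster exactly.  That
guarantee is what lets pipeline tolerances (+-2 points) be attributed to
boundary/morphology effects rather than segmentation failure.

Symptom painting
----------------
Necrotic blobs and white spots are random disks placed inside the silhouette
(spots with a safety margin from the boundary so they never bridge to the
background), with radii shrunk adaptively so the painted fraction lands
within +-1 percentage point of the request without overshoot.  Venation is a
deterministic recursive branching skeleton (depth = ``vein_depth``) of
width-2 strokes; deeper recursion adds strictly more vein pixels, giving a
monotone density sweep.  All randomness flows from a single
``numpy.random.default_rng(seed)`` stream, so output is bit-exact per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .imaging_core import BinaryMask, RgbImage

__all__ = [
    "CLASS_CODES",
    "LeafSpec",
    "GroundTruth",
    "generate",
    "generate_suite",
    "PRESETS",
]

#: pixel-class codes in the ground-truth raster
CLASS_CODES = {
    "background": 0,
    "tissue": 1,
    "chlorotic": 2,
    "necrotic": 3,
    "spot": 4,
    "vein": 5,
}

# 8-bit base colours per class and lighting mode; scaled for other depths.
_COLOURS_PANEL = {
    "background": (245, 245, 245),
    "tissue": (60, 160, 60),
    "necrotic": (45, 40, 50),
    "spot": (235, 232, 230),
    "vein": (80, 170, 80),
}
_COLOURS_BACKLIT = {
    "background": (250, 250, 250),
    "tissue": (70, 110, 90),
    "necrotic": (40, 35, 45),
    "spot": (235, 232, 230),
    "vein": (200, 210, 185),
}


@dataclass(frozen=True)
class LeafSpec:
    """Parameters of one synthetic leaf image."""

    height: int = 1024
    width: int = 1280
    seed: int = 0
    radius_frac: float = 0.33  #: base silhouette radius / min(height, width)
    lobes: int = 5
    lobe_amp: float = 0.12
    boundary_roughness: float = 0.0  #: relative radial noise amplitude
    chlorosis_level: float = 0.0  #: 0 = green, 1 = fully yellowed
    chlorosis_quadrant: int | None = None  #: 1..4 for localized; None = generalized
    necrotic_fraction: float = 0.0  #: target fraction of the silhouette
    spot_fraction: float = 0.0
    vein_depth: int = 0  #: branching recursion depth (0 = no venation)
    lighting: str = "panel"  #: "panel" or "backlit"
    bit_depth: int = 8
    jitter: int = 3  #: +-range of per-pixel colour noise (8-bit units)

    def __post_init__(self):
        for name in ("boundary_roughness", "chlorosis_level", "necrotic_fraction", "spot_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.necrotic_fraction + self.spot_fraction > 0.8:
            raise ValueError("necrotic + spot fractions exceed the paintable leaf area")
        if self.lighting not in ("panel", "backlit"):
            raise ValueError("lighting must be 'panel' or 'backlit'")
        if self.chlorosis_quadrant is not None and self.chlorosis_quadrant not in (1, 2, 3, 4):
            raise ValueError("chlorosis_quadrant must be 1..4 or None")
        if self.radius_frac * (1 + self.lobe_amp + self.boundary_roughness) >= 0.49:
            raise ValueError("silhouette would not fit inside the frame")


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-pixel classes and derived fractions for one generated leaf."""

    class_raster: np.ndarray  #: uint8 raster of CLASS_CODES
    silhouette: BinaryMask
    fractions: dict  #: necrotic/spot/vein/chlorotic fractions of the silhouette
    chlorotic_per_quadrant: tuple[float, float, float, float]
    analytic_area: float  #: area of the unperturbed polar silhouette
    analytic_perimeter: float
    spec: LeafSpec = field(repr=False)


def _radial_noise(rng: np.random.Generator, theta: np.ndarray) -> np.ndarray:
    """Band-limited periodic profile, normalized to unit peak amplitude."""
    profile = np.zeros_like(theta)
    for m in range(8, 25):
        amp = rng.normal(0.0, 1.0) / m
        phase = rng.uniform(0.0, 2.0 * np.pi)
        profile += amp * np.cos(m * theta + phase)
    peak = np.abs(profile).max()
    return profile / peak if peak > 0 else profile


def _paint_blobs(rng, class_raster, allowed, target_px, code, sil_count):
    """Place random disks of class ``code`` until the painted count is within
    ~0.5% of the silhouette of ``target_px`` (never overshooting it by more
    than one blob boundary)."""
    if target_px <= 0:
        return
    paintable = {CLASS_CODES["tissue"], CLASS_CODES["chlorotic"]}
    coords = np.argwhere(allowed)
    if len(coords) == 0:
        return
    h, w = class_raster.shape
    tol = max(0.003 * sil_count, 14.0)
    painted = 0
    for _ in range(4000):
        remaining = target_px - painted
        if remaining <= tol:
            break
        r = int(np.sqrt(remaining / np.pi) * rng.uniform(0.55, 1.0))
        r = max(2, min(r, h // 6))
        cy, cx = coords[rng.integers(len(coords))]
        r0, r1 = max(0, cy - r), min(h, cy + r + 1)
        c0, c1 = max(0, cx - r), min(w, cx + r + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        patch = class_raster[r0:r1, c0:c1]
        eligible = disk & allowed[r0:r1, c0:c1] & np.isin(patch, list(paintable))
        n_new = int(eligible.sum())
        if n_new == 0:
            continue
        if n_new > remaining + tol:  # adaptive shrink would overshoot; retry smaller
            continue
        patch[eligible] = code
        painted += n_new


def _vein_segments(spec: LeafSpec, radius: float, centre) -> list[tuple]:
    """Deterministic recursive branching skeleton: list of ((r0,c0),(r1,c1)).

    Branch geometry is fixed (no randomness), so the segment set for depth d
    is a strict subset of the set for depth d+1: the density sweep is nested.
    """
    segments: list[tuple] = []

    def rot(v, deg):
        a = np.deg2rad(deg)
        return np.array([v[0] * np.cos(a) - v[1] * np.sin(a), v[0] * np.sin(a) + v[1] * np.cos(a)])

    def branch(p0, direction, length, depth):
        if depth <= 0 or length < 3:
            return
        p1 = p0 + direction * length
        segments.append((tuple(p0), tuple(p1)))
        for i, t in enumerate((0.25, 0.45, 0.65, 0.85)):
            base = p0 + direction * (length * t)
            side = 1 if i % 2 == 0 else -1
            child_dir = rot(direction, side * 50.0)
            branch(base, child_dir, length * 0.45 * (1.1 - 0.4 * t), depth - 1)

    cr, cc = centre
    start = np.array([cr + 0.85 * radius, cc])
    branch(start, np.array([-1.0, 0.0]), 1.7 * radius, spec.vein_depth)
    return segments


def _draw_segments(segments, target, allowed):
    h, w = target.shape
    for (r0, c0), (r1, c1) in segments:
        n = max(2, int(2 * np.hypot(r1 - r0, c1 - c0)))
        rr = np.clip(np.round(np.linspace(r0, r1, n)).astype(int), 0, h - 1)
        cc = np.clip(np.round(np.linspace(c0, c1, n)).astype(int), 0, w - 1)
        for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):  # width-2 stroke
            r = np.clip(rr + dr, 0, h - 1)
            c = np.clip(cc + dc, 0, w - 1)
            ok = allowed[r, c]
            target[r[ok], c[ok]] = True


def _quadrant_masks(shape, centre):
    h, w = shape
    cr, cc = centre
    rows = np.arange(h)[:, None] < cr
    cols = np.arange(w)[None, :] < cc
    return [rows & cols, rows & ~cols, ~rows & cols, ~rows & ~cols]


def generate(spec: LeafSpec) -> tuple[RgbImage, GroundTruth]:
    """Render one synthetic leaf and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    centre = (h / 2.0, w / 2.0)
    radius = spec.radius_frac * min(h, w)

    yy, xx = np.mgrid[:h, :w].astype(np.float64)
    dy, dx = yy - centre[0], xx - centre[1]
    theta = np.arctan2(dy, dx)
    dist = np.hypot(dy, dx)

    noise = _radial_noise(rng, theta)
    r_theta = radius * (
        1.0 + spec.lobe_amp * np.cos(spec.lobes * theta) + spec.boundary_roughness * noise
    )
    silhouette = dist <= r_theta

    # analytic reference for the unperturbed (roughness-free) curve
    a, k = spec.lobe_amp, spec.lobes
    analytic_area = np.pi * radius**2 * (1.0 + a**2 / 2.0)
    tt = np.linspace(0.0, 2.0 * np.pi, 200_001)
    rr = radius * (1.0 + a * np.cos(k * tt))
    drr = -radius * a * k * np.sin(k * tt)
    analytic_perimeter = float(np.trapezoid(np.sqrt(rr**2 + drr**2), tt))

    classes = np.zeros((h, w), dtype=np.uint8)
    classes[silhouette] = CLASS_CODES["tissue"]
    sil_count = int(silhouette.sum())
    if sil_count == 0:
        raise ValueError("degenerate spec: empty silhouette")

    # chlorosis: recolour tissue, generalized or in one quadrant
    if spec.chlorosis_level > 0:
        if spec.chlorosis_quadrant is None:
            chl_region = silhouette
        else:
            quad = _quadrant_masks((h, w), centre)[spec.chlorosis_quadrant - 1]
            chl_region = silhouette & quad
        classes[chl_region & (classes == CLASS_CODES["tissue"])] = CLASS_CODES["chlorotic"]

    interior = ndimage.binary_erosion(silhouette, iterations=2)
    _paint_blobs(
        rng, classes, interior,
        int(round(spec.necrotic_fraction * sil_count)), CLASS_CODES["necrotic"], sil_count,
    )
    spot_zone = ndimage.binary_erosion(silhouette, iterations=4)
    _paint_blobs(
        rng, classes, spot_zone,
        int(round(spec.spot_fraction * sil_count)), CLASS_CODES["spot"], sil_count,
    )

    if spec.vein_depth > 0:
        vein = np.zeros((h, w), bool)
        _draw_segments(
            _vein_segments(spec, radius, centre), vein,
            ndimage.binary_erosion(silhouette, iterations=1),
        )
        vein &= np.isin(classes, [CLASS_CODES["tissue"], CLASS_CODES["chlorotic"]])
        classes[vein] = CLASS_CODES["vein"]

    # ---- render colours
    table = _COLOURS_PANEL if spec.lighting == "panel" else _COLOURS_BACKLIT
    base_tissue = np.array(table["tissue"], float)
    if spec.lighting == "panel":
        chl_colour = base_tissue + spec.chlorosis_level * np.array([160.0, 40.0, 0.0])
    else:
        chl_colour = base_tissue + spec.chlorosis_level * np.array([140.0, 60.0, 0.0])
    colour_by_code = np.zeros((6, 3))
    for name, code in CLASS_CODES.items():
        colour_by_code[code] = chl_colour if name == "chlorotic" else np.array(table[name], float)

    img8 = colour_by_code[classes]  # (H, W, 3) in 8-bit units
    if spec.jitter > 0:
        img8 = img8 + rng.integers(-spec.jitter, spec.jitter + 1, size=img8.shape)
    max_value = (1 << spec.bit_depth) - 1
    arr = np.clip(np.round(img8 * (max_value / 255.0)), 0, max_value).astype(np.int64)
    image = RgbImage.from_array(arr, bit_depth=spec.bit_depth)

    counts = {name: int((classes == code).sum()) for name, code in CLASS_CODES.items()}
    quads = _quadrant_masks((h, w), centre)
    chl_per_quad = []
    for q in quads:
        leaf_q = int((silhouette & q).sum())
        chl_q = int(((classes == CLASS_CODES["chlorotic"]) & q).sum())
        chl_per_quad.append(chl_q / leaf_q if leaf_q else 0.0)
    fractions = {
        "necrotic": counts["necrotic"] / sil_count,
        "spot": counts["spot"] / sil_count,
        "vein": counts["vein"] / sil_count,
        "chlorotic": counts["chlorotic"] / sil_count,
    }
    truth = GroundTruth(
        classes,
        BinaryMask(silhouette),
        fractions,
        tuple(chl_per_quad),
        analytic_area,
        analytic_perimeter,
        spec,
    )
    return image, truth


# ---------------------------------------------------------------------------
# Presets reproducing the experimental axes (sweeps) used for validation.


def _preset_specs(name: str, seed: int, height: int, width: int) -> list[LeafSpec]:
    base = LeafSpec(height=height, width=width, seed=seed)
    if name == "chlorosis":
        specs = [replace(base, chlorosis_level=lvl) for lvl in (0.0, 0.3, 0.7, 1.0)]
        specs.append(replace(base, chlorosis_level=0.9, chlorosis_quadrant=2))
        return specs
    if name == "necrosis":
        return [replace(base, necrotic_fraction=f) for f in (0.0, 0.05, 0.10, 0.25, 0.50)]
    if name == "deformation":
        # one silhouette noise realization (same seed), amplitude swept: nested shapes
        return [replace(base, boundary_roughness=r) for r in (0.0, 0.1, 0.2, 0.3)]
    if name == "spots":
        return [replace(base, spot_fraction=f) for f in (0.0, 0.02, 0.08, 0.20)]
    if name == "mosaic":
        return [
            replace(base, lighting="backlit", vein_depth=d) for d in (0, 2, 3, 4, 5, 6)
        ]
    raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")


PRESETS = ("chlorosis", "necrosis", "deformation", "spots", "mosaic")


def generate_suite(
    preset: str, seed: int = 0, height: int = 1024, width: int = 1280
) -> list[tuple[RgbImage, GroundTruth]]:
    """Generate the named sweep of leaves (see :data:`PRESETS`)."""
    return [generate(s) for s in _preset_specs(preset, seed, height, width)]
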