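# Methods

This note records the models, conventions and design choices behind each
pipeline, what the synthetic-data generator does and does not emulate, and the
known limitations.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Image model and conventions

Images are H×W rasters with integer red/green/blue channels at a declared
working bit depth (8 by default; 10 supported so the mosaic pipeline can work
on a 0–1023 grey scale).  All thresholds are expressed as fractions of the
channel maximum `max_value = 2^depth − 1`, never as hard-coded 8-bit numbers.

Pixels are addressed 0-based, row-major, `(i, j) = (row, column)`.  The
weighted centroid's `cx` is the **row** coordinate (it is weighted by the row
index) and `cy` the column coordinate.  This is documented loudly because the
quadrant partition of the chlorosis pipeline depends on it; note that both
chlorosis summaries are invariant to quadrant relabelling, so even a
transposed convention would change neither `R_n` nor `R_diff`.

Thresholding is strict (`>` / `<`); pixels equal to the threshold fall in
neither mask.  The generator places its colour bands away from the default
thresholds, and for real photographs the measure-zero tie set is immaterial.

Connected-component labelling (the "connectivity algorithm") defaults to
8-adjacency and is backed by `scipy.ndimage.label`; an independent BFS
flood-fill oracle verifies it in the tests.

## Morphology

Erosion/dilation/opening/closing and the two hat transforms are implemented
by reducing over shifted copies of the padded image, one pass per structuring
element cell.  Border conventions, which is where implementations genuinely
differ:

* **Binary erosion/dilation** use the literal set definitions on the finite
  pixel set: outside the frame is background.  Consequence: an element must
  fit inside the frame for erosion to keep a border pixel.
* **Binary opening/closing** are evaluated on an enlarged canvas and cropped,
  making them equal to the infinite-plane operators restricted to the frame.
  Without this, closing would not be extensive at the border.  With it, the
  full algebra holds on every fixture: opening is anti-extensive, increasing
  and idempotent; closing extensive and idempotent.
* **Grayscale operators** take the min/max over the in-frame part of the
  neighbourhood (erosion effectively padded with the range maximum, dilation
  with the minimum).  This pair is an adjunction on the frame, so the same
  algebra holds, and a constant image is a fixed point of both — hence both
  hat transforms are exactly zero on constant images, which the mosaic
  pipeline relies on.
* Complement-duality `δ_B(A) = ¬ε_C(¬A)` is a statement about the infinite
  plane; the tests assert it by embedding masks with a margin wider than the
  element (equivalently, by passing the matching pad value).

Default elements: 3×3 box for the necrosis pre-threshold opening (lesions of
interest are much larger than 3 px), 9×9 disk (radius 4) for the mosaic hats
(veins are ~2 px wide, well inside the disk).  Both are configurable; a small
text grid format (`rows of 0/1, origin marked 2`) and `box:n / disk:r /
cross:n` names are accepted.

The "median filter based on morphological opening" used before necrosis
thresholding is implemented as a grayscale opening — the formula, not the
name, is authoritative.

## Chlorosis

Quadrant means are computed over leaf pixels only by default (leaf mask from
blue-channel segmentation): including the bright panel would swamp the means.
A whole-frame mode (`masked=False`) keeps the literal definition available,
and it is the mode used for the closed-form checks (`R_n = 2v` on a uniform
image, `R_diff = 2|a−b|` on a half-plane image with central centroid).  The
partitioning centroid is taken from the whole-frame yellow image by default
(the literal definition), with an option to restrict it to the leaf mask.
Empty quadrants (possible with degenerate centroids) are excluded from both
moduli with a warning.  The tool reports raw `(R_n, R_diff)` in native
intensity units and deliberately defines no localized/generalized cutoff.

## Necrosis

Lesions are *dark* (brown/black), so the green channel is thresholded from
below (`t_necro = 0.35·max_value` by default).  The leaf silhouette comes
from the blue channel below `t_leaf = 0.80·max_value`, keeping the largest
connected component; necrotic pixels are counted inside the silhouette only.
The green channel of chlorotic tissue stays far above `t_necro`, which is the
reason this channel is used: yellowing does not inflate `A_n` (verified as a
confound test against generator ground truth).  The opening is applied to the
grayscale green channel before binarization, absorbing bright pixel noise
(salt) that would otherwise punch holes in the lesion mask.

## Deformation

The sphericity index `I = p²/(4πA)` needs a perimeter estimator that is
calibrated — a digitized circle must actually give `I ≈ 1`.  The outer
boundary is traced as an 8-connected Moore chain.  The plain chain length
(axial steps 1, diagonal steps √2) overestimates the length of a digital
straight edge at angle φ by `cosφ + (√2−1)sinφ − 1` per unit length, ~5.5%
averaged over orientations, which would push a disk to `I ≈ 1.11`.  The
default estimator therefore subtracts an analytically derived correction
`c = (2√2 − 2 − π/4) / [2(1 − 2/√5) + 2(√2 − 3/√5)] ≈ 0.1208` per 45°
direction change of the chain; this zeroes the mean orientation bias while
leaving purely axial boundaries exact (a 5×5 square still measures p = 16,
and large squares keep `I ≈ 4/π`).  Plain (`"chain"`) and unweighted
(`"raw"`) step counts remain available.  A single-pixel object is assigned
p = 4 (its unit square) by convention.  Interior holes are filled before
measurement: only the outer contour describes leaf shape.  The tool reports
raw `I` per leaf; comparing deformed against healthy leaves of the same
species is left to the user, since no normalized ratio is defined.

## White spots

One bright threshold (`0.80·max_value` on blue) splits the frame; then
*background* is defined as the bright components touching the frame border —
the only parameter-free rule that keeps interior spots out of the background
count — and the spotless leaf is the largest dark component.  `A_ws` follows
by the exact accounting identity, so stray dark debris outside the leaf is
booked as spot area; this is a documented artifact of the accounting, and an
optional closing of the bright mask (`denoise_se`) absorbs small debris.
Spots that touch the silhouette edge would merge with the background
brightness and follow the border-touching rule; the generator keeps spots
interior by construction.

## Mosaic

The back-lit blue channel is contrast-stretched onto the full working range,
then enhanced.  How the two hat transforms combine is a genuine design
choice; the default is the classical `s + Thw(s) − Thb(s)` (clamped), which
matches the stated purpose of boosting vein/lamina contrast, with a literal
"sequential replacement" mode kept as an option.  Edges come from an
in-package Canny (Gaussian σ = 1.4, Sobel gradients, 4-sector non-maximum
suppression with one-sided tie-breaking so straight edges are 1 px thin,
double-threshold hysteresis).  The hysteresis thresholds are *fractions of
the maximum gradient magnitude* (defaults 0.10 / 0.25), which makes the edge
set invariant to residual global brightness/contrast shifts.  Since
hysteresis output is already binary, no further binarization is applied.
Leaf-outline edges are included in `A_map`; for a venation-free leaf they are
the only contribution (roughly perimeter/area of the silhouette, well under
2% on frame-filling leaves).  Mosaic analysis requires an explicit back-lit
flag: the imaging mode cannot be inferred reliably from pixels.

## Synthetic leaf generator

The generator exists to make every pipeline verifiable with pixel-exact
ground truth.  Choices:

* **Silhouette**: star-shaped polar curve `r(θ) = R(1 + a·cos kθ + ρ·g(θ))`
  (defaults k = 5 lobes, a = 0.12, base radius 0.33·min(H,W)), with `g` a
  seeded band-limited harmonic profile (orders 8–24, unit peak) scaled by the
  relative roughness ρ ∈ [0, 0.3].  Analytic area `πR²(1 + a²/2)` and a
  high-resolution numeric perimeter integral of the unperturbed curve are
  stored in the ground truth.  Within a sweep the same seed is reused, so
  increasing ρ scales one fixed noise profile — shapes are nested and the
  perimeter strictly grows.
* **Colour bands** (8-bit units, scaled for 10-bit): panel background
  (245,245,245), tissue (60,160,60), chlorotic tissue interpolating to
  (220,200,60) at level 1, necrotic (45,40,50), spots (235,232,230); back-lit
  lamina (70,110,90), veins (200,210,185), panel (250,250,250).  Per-pixel
  jitter of ±3 grey levels is added.  In every thresholded channel the bands
  on either side of the default threshold stay >30 grey levels apart after
  jitter, so default-threshold segmentation recovers the class raster
  *exactly*; any pipeline error beyond that is attributable to morphology and
  boundary effects, not segmentation.
* **Lesions/spots**: random disks with adaptively shrinking radii, placed
  inside the silhouette (spots with a 4-px interior margin) until the painted
  fraction is within ±1 percentage point of the request, without overshoot.
* **Venation**: a deterministic recursive branching skeleton (4 children per
  segment, 50° branch angle, 0.45 length decay) drawn as width-2 strokes;
  branch geometry carries no randomness, so depth-d veins are a strict subset
  of depth-(d+1) veins and the density sweep is exactly nested.
* One `numpy.random.default_rng(seed)` stream per image; output is bit-exact
  per seed.

What the generator does **not** emulate: natural colour texture and gradients
within tissue, specular highlights, shadows, petioles, overlapping or tilted
leaves, lens distortion, demosaicing artifacts, and continuous symptom
boundaries (real chlorosis grades into green; generated classes are crisp
bands).  Passing tests therefore demonstrate that the algorithms are
implemented correctly and recover known truth under clean, well-separated
imaging conditions — they do not certify accuracy on field photographs, where
threshold tuning to the light conditions is expected.

## Problem sizes and defaults used in verification

The test suite and the acceptance script run the severity sweeps at the full
1280×1024 sensor frame (24 images across five sweeps); unit tests use
320×256 frames for speed.  Calibration shapes are a digitized disk of radius
200 (plus 100/400 for the convergence check) and a 200-px square.  Exhaustive
morphology checks cover all 512 3×3 binary images with the 3×3 cross element
and 100 random 16×16 grayscale images with random elements up to 5×5.

## Known limitations

* All five pipelines assume one leaf per frame on a bright uniform panel;
  `A_TL`-style largest-component rules silently pick the biggest object if
  several are present.
* Fixed global thresholds (user-adjustable) rather than adaptive ones; under
  uneven illumination the blue-channel leaf mask degrades first.
* The deformation index conflates boundary roughness with elongation: a
  smooth but narrow leaf also scores I > 1.
* Necrosis cannot be distinguished from dark shadows or soil inside the leaf
  mask; mosaic edge counts include the leaf outline and any sharp lesion
  boundaries present in a back-lit frame.
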