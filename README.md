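# leafquant

Quantification of the five common visual symptoms of diseased and
malnourished plants — **chlorosis**, **necrosis**, **leaf deformation**,
**white spots** and **vein-clearing mosaic** — from RGB leaf photographs.

Visual scoring of plant symptoms by human raters is subjective and
imprecise; colour-based image analysis replaces it with reproducible
numbers.  `leafquant` is aimed at plant-pathology and plant-nutrition
work (disease severity assessment, fertilizer trials, resistance
screening) where leaves are photographed against a uniform bright panel
(front-lit for most symptoms, back-lit for venation).  It is a pure
software library + CLI: no camera or acquisition hardware is involved.

## The five measurements

With `Red/Green/Blue` the colour channels of an H×W image and a working
bit depth of 8 (0–255) or 10 (0–1023):

**Chlorosis** (yellowing).  The yellow component `Yellow = 0.5·Red + 0.5·Green`
is split into four quadrants around its intensity-weighted centroid
(C_x, C_y).  With R_k the mean yellow level of quadrant k:

    R_n    = ‖[R_1, R_2, R_3, R_4]‖                       (overall chlorosis level)
    R_diff = ‖[R_1−R_2, R_1−R_3, R_1−R_4,
               R_2−R_3, R_2−R_4, R_3−R_4]‖                (localization: ≈0 when generalized)

**Necrosis** (dark lesions).  Green channel → grayscale morphological
opening γ_B (denoising) → dark-object threshold inside the leaf
silhouette (blue-channel segmentation):

    A_n = 100 · A_np / A_T   [%]

**Deformation**.  Sphericity index of the leaf silhouette with area A
and outer perimeter p (pixels):

    I = p² / (4πA)      (circle → 1; axis-aligned square → 4/π ≈ 1.273)

**White spots** (bright lesions).  One bright threshold on the blue
channel plus connected-component accounting: background A_BG = bright
components touching the frame border, spotless leaf A_TL = largest dark
component, and with frame size A_ZS:

    A_ws  = A_ZS − A_BG − A_TL
    A_pws = 100 · A_ws / (A_TL + A_ws)   [%]

**Mosaic** (vein clearing, back-lit).  Blue channel → contrast stretch to
the full grey range → top-hat/bottom-hat enhancement
(`s + Thw_B(s) − Thb_B(s)`) → Canny edge detection → edge pixels inside
the leaf:

    A_mosaic = 100 · A_map / A_TL   [%]

The morphological operators (erosion, dilation, opening, closing,
top-hat, bottom-hat) are implemented in-package and verified against
brute-force set/min-max definitions; see `docs/methods.md` for all
numerical conventions.

A built-in synthetic diseased-leaf generator (`leafquant.synth_leaf`)
renders leaves with exact per-pixel ground truth for every symptom, which
is what the test suite measures the pipelines against.

## Worked example

Generate a full-frame synthetic leaf with 10% necrotic area and moderate
generalized chlorosis, then analyze it:

```python
from leafquant import LeafSpec, generate, write_rgb
img, truth = generate(LeafSpec(seed=42, necrotic_fraction=0.10,
                               chlorosis_level=0.4, height=1024, width=1280))
write_rgb("leaf.png", img)
```

```
$ leafquant all --out report.json leaf.png
```

`report.json` then contains (abridged):

```json
{
  "chlorosis":   {"rn": 279.32, "rdiff": 23.92,
                  "region_means": [140.56, 134.08, 148.90, 134.58]},
  "necrosis":    {"a_np": 35802, "a_t": 361338, "a_n": 9.91},
  "deformation": {"area_px": 361338, "perimeter_px": 2301.31, "index": 1.166},
  "white_spots": {"a_zs": 1310720, "a_bg": 949382, "a_tl": 361338,
                  "a_ws": 0, "a_pws": 0.0}
}
```

Reading the numbers: `a_n = 9.91%` recovers the painted 10% lesion
fraction; `rn = 279.3` sits between the all-green (≈220) and fully
yellow (≈420) extremes, consistent with the 0.4 chlorosis level, while
`rdiff = 23.9` is non-zero only because the dark lesions are unevenly
spread over the quadrants; `index = 1.166` reflects the lobed (but
unroughened) silhouette; no white spots were painted, so `a_pws = 0`.
Mosaic is skipped with a warning unless the image is flagged `--backlit`.

Other subcommands: `leafquant {chlorosis|necrosis|deformation|white-spots|mosaic}`
for a single pipeline, and `leafquant synth --preset necrosis --out-dir d/`
to render the synthetic sweeps with their ground truth.  All thresholds
and structuring elements can be overridden on the command line or with
`--config file` (flat `key=value` format); every report embeds the
parameters and a config hash so results are exactly reproducible.

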