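import warnings

import numpy as np
import pytest
from oracles import centroid_loops, flood_fill_label

from conftest import uniform_rgb
from leafquant import (
    BinaryMask,
    GrayImage,
    LeafQuantError,
    RgbImage,
    binarize,
    compute_yellow,
    connected_components,
    contrast_stretch,
    extract_channel,
    read_rgb,
    weighted_centroid,
    write_mask,
    write_rgb,
)


class TestYellowComponent:
    @pytest.mark.parametrize(
        "r, g, b, expected",
        [(255, 0, 0, 127.5), (200, 200, 17, 200.0), (0, 0, 255, 0.0)],
    )
    def test_pixel_values(self, r, g, b, expected):
        y = compute_yellow(uniform_rgb(r, g, b, (2, 3)))
        assert np.allclose(y.values, expected)

    def test_uniform_identity(self):
        y = compute_yellow(uniform_rgb(93, 93, 5))
        assert np.all(y.values == 93.0)

    def test_linearity(self, rng):
        arr = rng.integers(0, 120, size=(9, 7, 3))
        img1 = RgbImage.from_array(arr)
        img2 = RgbImage.from_array(arr * 2)
        assert np.allclose(compute_yellow(img2).values, 2 * compute_yellow(img1).values)


class TestExtractChannel:
    def test_channels(self):
        img = uniform_rgb(10, 20, 30)
        assert np.all(extract_channel(img, "blue").values == 30)
        assert np.all(extract_channel(img, "green").values == 20)
        assert np.all(extract_channel(img, "red").values == 10)

    def test_unknown_channel(self):
        with pytest.raises(ValueError, match="unknown channel"):
            extract_channel(uniform_rgb(1, 2, 3), "alpha")

    def test_background_brighter_than_leaf_in_blue(self, clean_leaf):
        img, truth = clean_leaf
        blue = extract_channel(img, "blue").values
        sil = truth.silhouette.values
        assert blue[~sil].min() > blue[sil].max()


class TestContrastStretch:
    def test_three_values_to_ten_bit(self):
        img = GrayImage(np.array([[0.0, 128.0, 255.0]]), (0, 255))
        out = contrast_stretch(img, 0, 1023)
        assert np.allclose(out.values, [[0.0, 128 / 255 * 1023, 1023.0]])

    def test_two_values_map_to_endpoints(self):
        img = GrayImage(np.array([[100.0, 200.0]]), (0, 255))
        out = contrast_stretch(img, 0, 1023)
        assert np.allclose(out.values, [[0.0, 1023.0]])

    def test_full_range_is_identity(self, rng):
        v = rng.uniform(0, 255, (6, 6))
        v[0, 0], v[-1, -1] = 0.0, 255.0
        img = GrayImage(v, (0, 255))
        assert np.allclose(contrast_stretch(img, 0, 255).values, v)

    def test_monotone(self, rng):
        v = rng.uniform(0, 255, (8, 8))
        out = contrast_stretch(GrayImage(v, (0, 255)), 0, 1023).values
        order_in = np.argsort(v.ravel())
        assert np.all(np.diff(out.ravel()[order_in]) >= 0)

    def test_constant_image_warns_and_returns_midpoint(self):
        img = GrayImage(np.full((3, 3), 7.0), (0, 255))
        with pytest.warns(UserWarning, match="constant"):
            out = contrast_stretch(img, 0, 1023)
        assert np.all(out.values == 511.5)


class TestBinarize:
    def test_above(self):
        img = GrayImage(np.array([[10.0, 200.0]]), (0, 255))
        assert binarize(img, 100, "above").values.tolist() == [[False, True]]

    def test_threshold_at_max_gives_empty(self, rng):
        v = rng.uniform(0, 255, (5, 5))
        assert not binarize(GrayImage(v, (0, 255)), 255, "above").values.any()

    def test_strict_ties_excluded_and_partition(self, rng):
        v = rng.integers(0, 10, (12, 12)).astype(float)
        img = GrayImage(v, (0, 255))
        above = binarize(img, 5, "above").values
        below = binarize(img, 5, "below").values
        assert not (above & below).any()
        assert np.array_equal(above | below | (v == 5), np.ones_like(above))

    def test_band_midpoint_recovers_generator_classes(self, spotted_leaf):
        # intensity bands are disjoint by construction: thresholding the blue
        # channel midway recovers background+spots exactly
        img, truth = spotted_leaf
        bright = binarize(extract_channel(img, "blue"), 0.8 * img.max_value, "above")
        expected = np.isin(truth.class_raster, [0, 4])  # background, spot
        assert np.array_equal(bright.values, expected)


class TestConnectedComponents:
    def test_diagonal_pixels_connectivity(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = m[2, 2] = True
        assert connected_components(BinaryMask(m), 4).n_components == 2
        assert connected_components(BinaryMask(m), 8).n_components == 1

    def test_empty_mask(self):
        res = connected_components(BinaryMask(np.zeros((3, 3), bool)), 8)
        assert res.n_components == 0

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(5):
            m = rng.random((32, 32)) < 0.45
            got = connected_components(BinaryMask(m), connectivity)
            want = flood_fill_label(m, connectivity)
            assert got.n_components == want.max()
            # same partition up to label renaming
            pairs = set(zip(got.labels[m].tolist(), want[m].tolist()))
            assert len(pairs) == want.max()
            assert got.sizes.sum() == m.sum()

    def test_border_touching_flags(self):
        m = np.zeros((5, 5), bool)
        m[0, 0] = True  # touches border
        m[2, 2] = True  # interior
        res = connected_components(BinaryMask(m), 8)
        by_size = {res.labels[0, 0]: True, res.labels[2, 2]: False}
        for k, expect in by_size.items():
            assert res.border_touching[k - 1] == expect


class TestWeightedCentroid:
    def test_uniform_is_geometric_centre(self):
        img = GrayImage(np.ones((11, 11)), (0, 255))
        c = weighted_centroid(img)
        assert (c.cx, c.cy) == (5.0, 5.0)

    def test_single_pixel(self):
        v = np.zeros((10, 10))
        v[3, 7] = 42.0
        c = weighted_centroid(GrayImage(v, (0, 255)))
        assert (c.cx, c.cy) == (3.0, 7.0)

    def test_matches_double_loop_oracle(self, rng):
        v = rng.uniform(0, 255, (16, 16))
        c = weighted_centroid(GrayImage(v, (0, 255)))
        ox, oy = centroid_loops(v)
        assert abs(c.cx - ox) < 1e-9 * abs(ox)
        assert abs(c.cy - oy) < 1e-9 * abs(oy)

    def test_zero_intensity_errors(self):
        with pytest.raises(LeafQuantError, match="zero total intensity"):
            weighted_centroid(GrayImage(np.zeros((4, 4)), (0, 255)))


class TestContainers:
    def test_rgb_invariants(self):
        with pytest.raises(ValueError):
            RgbImage(np.zeros((2, 2), int), np.zeros((2, 3), int), np.zeros((2, 2), int))
        with pytest.raises(ValueError):
            uniform_rgb(300, 0, 0)  # out of 8-bit range
        img = uniform_rgb(1000, 0, 0, bit_depth=10)
        assert img.max_value == 1023

    def test_gray_range_checked(self):
        with pytest.raises(ValueError):
            GrayImage(np.array([[5.0]]), (0, 4))


class TestIO:
    def test_rgb_png_round_trip(self, tmp_path, rng):
        arr = rng.integers(0, 256, size=(10, 12, 3))
        img = RgbImage.from_array(arr)
        path = tmp_path / "img.png"
        write_rgb(path, img)
        back = read_rgb(path)
        assert np.array_equal(back.to_array(), img.to_array())

    def test_mask_export(self, tmp_path):
        import imageio.v3 as iio

        m = BinaryMask(np.eye(4, dtype=bool))
        path = tmp_path / "mask.png"
        write_mask(path, m)
        assert np.array_equal(iio.imread(path) > 0, m.values)

    def test_sixteen_bit_tiff_down_interpreted(self, tmp_path):
        import imageio.v3 as iio

        arr16 = np.full((4, 4, 3), 65535, dtype=np.uint16)
        path = tmp_path / "img.tiff"
        iio.imwrite(path, arr16)
        img = read_rgb(path, bit_depth=10)
        assert img.max_value == 1023
        assert int(img.red.max()) == 1023
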