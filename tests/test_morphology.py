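import numpy as np
import pytest
import oracles

from leafquant import (
    BinaryMask,
    GrayImage,
    StructuringElement,
    bottom_hat,
    close,
    dilate,
    erode,
    open_,
    top_hat,
)


def bm(arr):
    return BinaryMask(np.asarray(arr, bool))


def gi(arr, rng=(0.0, 255.0)):
    return GrayImage(np.asarray(arr, float), rng)


class TestStructuringElement:
    def test_constructors(self):
        assert StructuringElement.box(3).pattern.sum() == 9
        assert StructuringElement.cross(3).pattern.sum() == 5
        d = StructuringElement.disk(4)
        assert d.pattern.shape == (9, 9)
        assert d.pattern[4, 4] and d.pattern[0, 4] and not d.pattern[0, 0]

    def test_reflect_involution(self, rng):
        pattern, origin = oracles.random_se(rng)
        se = StructuringElement(pattern, origin)
        back = se.reflect().reflect()
        assert np.array_equal(back.pattern, se.pattern)
        assert back.origin == se.origin

    def test_invalid(self):
        with pytest.raises(ValueError):
            StructuringElement(np.zeros((3, 3), bool), (1, 1))
        with pytest.raises(ValueError):
            StructuringElement(np.ones((3, 3), bool), (3, 0))

    def test_text_round_trip(self):
        se = StructuringElement.cross(3)
        back = StructuringElement.from_text(se.to_text())
        assert np.array_equal(back.pattern, se.pattern)
        assert back.origin == se.origin


class TestExamples:
    def test_erode_all_true_3x3_box_keeps_centre_only(self):
        out = erode(bm(np.ones((3, 3))), StructuringElement.box(3))
        want = np.zeros((3, 3), bool)
        want[1, 1] = True
        assert np.array_equal(out.values, want)

    def test_single_cell_se_is_identity(self, rng):
        m = bm(rng.random((6, 6)) < 0.5)
        se = StructuringElement.box(1)
        assert np.array_equal(erode(m, se).values, m.values)
        assert np.array_equal(dilate(m, se).values, m.values)
        assert np.array_equal(close(m, se).values, m.values)

    def test_dilate_single_pixel_gives_box(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        out = dilate(bm(m), StructuringElement.box(3))
        assert out.values.sum() == 9
        assert out.values[1:4, 1:4].all()

    def test_open_removes_small_speck(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        assert not open_(bm(m), StructuringElement.box(3)).values.any()

    def test_open_keeps_large_rectangle(self):
        m = np.zeros((10, 10), bool)
        m[2:8, 2:9] = True
        out = open_(bm(m), StructuringElement.box(3))
        assert np.array_equal(out.values, m)

    def test_close_fills_small_hole(self):
        m = np.ones((9, 9), bool)
        m[4, 4] = False
        out = close(bm(m), StructuringElement.box(3))
        assert out.values[4, 4]
        assert out.values.all()

    def test_hats_of_constant_are_zero(self):
        img = gi(np.full((7, 7), 42.0))
        se = StructuringElement.box(3)
        assert np.all(top_hat(img, se).values == 0)
        assert np.all(bottom_hat(img, se).values == 0)

    def test_top_hat_extracts_thin_bright_ridge(self):
        v = np.full((11, 11), 10.0)
        v[:, 5] = 200.0  # ridge thinner than the 5x5 element
        out = top_hat(gi(v), StructuringElement.box(5)).values
        assert np.all(out[:, 5] == 190.0)
        assert np.all(out[:, :4] == 0)

    def test_bottom_hat_extracts_thin_dark_valley(self):
        v = np.full((11, 11), 200.0)
        v[:, 5] = 10.0
        out = bottom_hat(gi(v), StructuringElement.box(5)).values
        assert np.all(out[:, 5] == 190.0)
        assert np.all(out[:, :4] == 0)

    def test_empty_se_rejected(self):
        with pytest.raises(ValueError):
            StructuringElement(np.zeros((2, 2), bool), (0, 0))


class TestOracleEquivalence:
    """Random fixtures against the brute-force set/min-max definitions.

    (The exhaustive 3x3 sweep lives in the acceptance suite.)
    """

    def test_binary_ops_match_oracle(self, rng):
        for _ in range(20):
            m = rng.random((16, 16)) < 0.5
            pattern, origin = oracles.random_se(rng)
            se = StructuringElement(pattern, origin)
            assert np.array_equal(erode(bm(m), se).values, oracles.binary_erode(m, pattern, origin))
            assert np.array_equal(dilate(bm(m), se).values, oracles.binary_dilate(m, pattern, origin))
            assert np.array_equal(open_(bm(m), se).values, oracles.binary_open(m, pattern, origin))
            assert np.array_equal(close(bm(m), se).values, oracles.binary_close(m, pattern, origin))

    def test_gray_ops_match_oracle(self, rng):
        for _ in range(10):
            v = rng.uniform(0, 255, (12, 12))
            pattern, origin = oracles.random_se(rng)
            se = StructuringElement(pattern, origin)
            img = gi(v)
            assert np.array_equal(erode(img, se).values, oracles.gray_erode(v, pattern, origin))
            assert np.array_equal(dilate(img, se).values, oracles.gray_dilate(v, pattern, origin))
            assert np.array_equal(top_hat(img, se).values, oracles.gray_top_hat(v, pattern, origin))
            assert np.array_equal(
                bottom_hat(img, se).values, oracles.gray_bottom_hat(v, pattern, origin)
            )


class TestAlgebra:
    def test_binary_duality_on_plane_embedding(self, rng):
        # dilate(A, B) = NOT erode(NOT A, reflect(B)) holds on the infinite
        # plane; asserted by embedding the mask with a margin wider than the
        # element so the frame border cannot interfere.
        for _ in range(10):
            m = rng.random((10, 10)) < 0.5
            pattern, origin = oracles.random_se(rng)
            se = StructuringElement(pattern, origin)
            margin = 6
            big = np.zeros((10 + 2 * margin, 10 + 2 * margin), bool)
            big[margin:-margin, margin:-margin] = m
            lhs = dilate(bm(big), se).values
            rhs = ~erode(bm(~big), se.reflect(), pad=True).values
            sl = slice(margin, -margin)
            assert np.array_equal(lhs[sl, sl], rhs[sl, sl])

    def test_gray_duality(self, rng):
        for _ in range(5):
            v = rng.uniform(0, 255, (9, 9))
            pattern, origin = oracles.random_se(rng)
            se = StructuringElement(pattern, origin)
            lhs = dilate(gi(v), se).values
            rhs = 255.0 - erode(gi(255.0 - v), se.reflect()).values
            assert np.allclose(lhs, rhs)

    def test_opening_anti_extensive_increasing_idempotent(self, rng):
        se = StructuringElement.cross(3)
        for _ in range(10):
            v = rng.uniform(0, 255, (10, 10))
            a, b = gi(v), gi(np.minimum(v, rng.uniform(0, 255, (10, 10))))
            ga = open_(a, se).values
            assert np.all(ga <= v + 1e-12)  # anti-extensive
            assert np.all(open_(b, se).values <= ga + 1e-12)  # increasing (b <= a)
            assert np.allclose(open_(gi(ga), se).values, ga)  # idempotent

    def test_closing_extensive_idempotent(self, rng):
        se = StructuringElement.cross(3)
        for _ in range(10):
            v = rng.uniform(0, 255, (10, 10))
            cv = close(gi(v), se).values
            assert np.all(cv >= v - 1e-12)
            assert np.allclose(close(gi(cv), se).values, cv)
        for _ in range(10):
            m = rng.random((10, 10)) < 0.5
            cm = close(bm(m), se).values
            assert np.all(cm >= m)  # extensive even at the border
            assert np.array_equal(close(bm(cm), se).values, cm)

    def test_hats_non_negative(self, rng):
        for _ in range(10):
            v = rng.uniform(0, 255, (10, 10))
            pattern, origin = oracles.random_se(rng)
            se = StructuringElement(pattern, origin)
            assert np.all(top_hat(gi(v), se).values >= -1e-12)
            assert np.all(bottom_hat(gi(v), se).values >= -1e-12)
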