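import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from desmoke import priors
from tests.conftest import rand_image


def brute_force_interchannel(img):
    total = 0.0
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            r, g, b = img[i, j]
            total += abs(r - g) + abs(g - b) + abs(b - r)
    return total / (img.shape[0] * img.shape[1])


def brute_force_dark_channel(img, patch):
    h, w = img.shape[:2]
    half = patch // 2
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            i0, i1 = max(0, i - half), min(h, i + half + 1)
            j0, j1 = max(0, j - half), min(w, j + half + 1)
            out[i, j] = img[i0:i1, j0:j1].min()
    return out


class TestInterchannel:
    @pytest.mark.parametrize("pixel,expected", [
        ((0.5, 0.5, 0.5), 0.0),
        ((1.0, 0.0, 0.0), 2.0),
        ((0.8, 0.5, 0.2), 1.2),
    ])
    def test_pixel_examples(self, pixel, expected):
        assert priors.interchannel_pixel(pixel) == pytest.approx(expected)

    @given(st.tuples(*[st.floats(0, 1) for _ in range(3)]))
    @settings(deadline=None, max_examples=50)
    def test_channel_permutation_symmetry(self, pixel):
        base = priors.interchannel_pixel(pixel)
        for perm in itertools.permutations(pixel):
            assert priors.interchannel_pixel(perm) == pytest.approx(base)

    def test_zero_iff_achromatic(self):
        assert priors.interchannel_pixel((0.3, 0.3, 0.3)) == 0.0
        assert priors.interchannel_pixel((0.3, 0.3, 0.30001)) > 0.0

    def test_grayscale_image_is_zero(self, rng):
        gray = np.repeat(rng.random((8, 8, 1)), 3, axis=2)
        assert priors.interchannel_image(gray) == 0.0

    def test_two_pixel_example(self):
        img = np.array([[[1.0, 0.0, 0.0], [0.5, 0.5, 0.5]]])
        assert priors.interchannel_image(img) == pytest.approx(1.0)

    def test_matches_per_pixel_loop(self, rng):
        for _ in range(50):
            img = rand_image(rng, 8, 8)
            assert priors.interchannel_image(img) == pytest.approx(
                brute_force_interchannel(img), abs=1e-12)


class TestDarkChannel:
    def test_all_white_is_one(self):
        assert np.all(priors.dark_channel(np.ones((8, 8, 3)), 3) == 1.0)

    def test_zero_channel_everywhere_gives_zero(self, rng):
        img = rand_image(rng, 10, 10)
        kill = rng.integers(0, 3, size=(10, 10))
        for c in range(3):
            img[..., c][kill == c] = 0.0
        assert np.all(priors.dark_channel(img, 5) == 0.0)

    @pytest.mark.parametrize("patch", [3, 5])
    def test_matches_double_loop_oracle(self, rng, patch):
        img = rand_image(rng, 16, 16)
        got = priors.dark_channel(img, patch)
        assert np.array_equal(got, brute_force_dark_channel(img, patch))

    def test_pointwise_monotone(self, rng):
        lo = rand_image(rng, 12, 12) * 0.5
        hi = np.clip(lo + rng.random((12, 12, 3)) * 0.3, 0, 1)
        assert np.all(priors.dark_channel(lo, 3) <= priors.dark_channel(hi, 3))

    @pytest.mark.parametrize("patch", [0, 2, 4])
    def test_even_or_nonpositive_patch_rejected(self, patch):
        with pytest.raises(ValueError):
            priors.dark_channel(np.ones((4, 4, 3)), patch)


class TestSoftMatting:
    def test_matches_dense_direct_solve(self, rng):
        guide = rand_image(rng, 8, 8)
        raw = rng.random((8, 8))
        eps = 1e-4
        L = priors.matting_laplacian(guide).toarray()
        dense = np.linalg.solve(L + eps * np.eye(64), eps * raw.ravel())
        got = priors.refine_dark_channel(raw, guide, eps=eps)
        assert np.abs(got - np.clip(dense.reshape(8, 8), 0, 1)).max() < 1e-6

    def test_constant_map_is_fixed_point(self, rng):
        guide = rand_image(rng, 8, 8)
        out = priors.refine_dark_channel(np.full((8, 8), 0.37), guide)
        assert np.abs(out - 0.37).max() < 1e-6

    def test_large_eps_returns_raw(self, rng):
        guide = rand_image(rng, 8, 8)
        raw = rng.random((8, 8))
        out = priors.refine_dark_channel(raw, guide, eps=1e7)
        assert np.abs(out - raw).max() < 1e-5

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            priors.refine_dark_channel(np.zeros((4, 4)), rand_image(rng, 8, 8))

    def test_laplacian_rows_sum_to_zero(self, rng):
        L = priors.matting_laplacian(rand_image(rng, 6, 6))
        assert np.abs(np.asarray(L.sum(axis=1))).max() < 1e-12


class TestTrimmedMean:
    def test_zero_trim_is_plain_mean(self, rng):
        vals = rng.random(37)
        assert priors.trimmed_mean(vals, 0.0) == pytest.approx(vals.mean())

    def test_decile_trim_example(self):
        assert priors.trimmed_mean(np.arange(10), 0.1) == pytest.approx(4.5)

    def test_permutation_invariant(self, rng):
        vals = rng.random(50)
        shuffled = rng.permutation(vals)
        assert priors.trimmed_mean(vals, 0.1) == pytest.approx(
            priors.trimmed_mean(shuffled, 0.1))

    def test_empty_and_bad_frac_rejected(self):
        with pytest.raises(ValueError):
            priors.trimmed_mean([], 0.1)
        with pytest.raises(ValueError):
            priors.trimmed_mean([1.0, 2.0], 0.5)
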