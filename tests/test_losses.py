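import numpy as np
import pytest

from desmoke import losses, priors
from desmoke.losses import LossWeights, TranslationDirection
from tests.conftest import rand_image


class TestAdversarial:
    @pytest.mark.parametrize("scores,real,expected", [
        (np.ones((4, 4)), True, 0.0),
        (np.zeros((4, 4)), True, 1.0),
        (np.full((4, 4), 0.5), True, 0.25),
        (np.full((4, 4), 0.5), False, 0.25),
    ])
    def test_lsgan_examples(self, scores, real, expected):
        assert losses.adversarial_loss(scores, real) == pytest.approx(expected)

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            losses.adversarial_loss(np.array([np.nan]), True)

    def test_log_objective_known_values(self):
        # D(real)=e^-1, D(fake)=1-e^-2 -> log terms -1 and -2
        got = losses.gan_log_objective(np.full(3, np.exp(-1.0)),
                                       np.full(3, 1 - np.exp(-2.0)))
        assert got == pytest.approx(-3.0)


class TestCycle:
    def test_perfect_reconstruction(self, rng):
        x, y = rand_image(rng), rand_image(rng)
        assert losses.cycle_loss(x, x, y, y) == 0.0

    def test_unit_error_example(self, rng):
        y = rand_image(rng, 4, 4)
        x = np.zeros((4, 4, 3))
        assert losses.cycle_loss(x, np.ones_like(x), y, y) == pytest.approx(1.0)

    def test_symmetric_in_cycle_roles(self, rng):
        x, xr = rand_image(rng), rand_image(rng)
        y, yr = rand_image(rng), rand_image(rng)
        assert losses.cycle_loss(x, xr, y, yr) == pytest.approx(
            losses.cycle_loss(y, yr, x, xr))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            losses.cycle_loss(rand_image(rng, 4, 4), rand_image(rng, 5, 5),
                              rand_image(rng), rand_image(rng))


class TestICMap:
    @pytest.mark.parametrize("v,direction,expected", [
        (1.0, TranslationDirection.HAZY_TO_CLEAR, 0.0),
        (1.0, TranslationDirection.CLEAR_TO_HAZY, 1.0),
        (0.3, TranslationDirection.HAZY_TO_CLEAR, 0.7),
        (0.0, TranslationDirection.CLEAR_TO_HAZY, 0.0),
    ])
    def test_boundary_map(self, v, direction, expected):
        assert losses.ic_direction_map(v, direction) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            losses.ic_direction_map(-0.1, TranslationDirection.HAZY_TO_CLEAR)


class TestICLoss:
    def test_achromatic_generations(self, rng):
        gray = np.repeat(rng.random((6, 6, 1)), 3, axis=2)
        # clear->hazy term 0, hazy->clear term 1
        assert losses.ic_loss(gray, gray) == pytest.approx(1.0)

    def test_matches_scalar_composition(self, rng):
        for _ in range(10):
            fh, fc = rand_image(rng), rand_image(rng)
            want = (losses.ic_direction_map(
                        priors.interchannel_image(fh) / 2,
                        TranslationDirection.CLEAR_TO_HAZY)
                    + losses.ic_direction_map(
                        priors.interchannel_image(fc) / 2,
                        TranslationDirection.HAZY_TO_CLEAR))
            assert losses.ic_loss(fh, fc) == pytest.approx(want, abs=1e-12)


class TestDCLoss:
    def test_zero_dark_channel_images(self, rng):
        img = rand_image(rng, 10, 10)
        img[..., 0] = 0.0
        assert losses.dc_loss(img, img, patch=3) == 0.0

    def test_all_white_images(self):
        white = np.ones((10, 10, 3))
        assert losses.dc_loss(white, white, patch=3) == pytest.approx(2.0)

    def test_matches_prior_composition(self, rng):
        for _ in range(5):
            fh, fc = rand_image(rng), rand_image(rng)
            want = sum(priors.trimmed_mean(priors.dark_channel(im, 5), 0.02)
                       for im in (fc, fh))
            got = losses.dc_loss(fh, fc, patch=5, trim_frac=0.02)
            assert got == pytest.approx(want, abs=1e-9)

    def test_hazy_term_ablatable(self, rng):
        fh, fc = rand_image(rng), rand_image(rng)
        without = losses.dc_loss(fh, fc, patch=5, include_hazy_term=False)
        want = priors.trimmed_mean(priors.dark_channel(fc, 5), 0.01)
        assert without == pytest.approx(want)


class TestTotalObjective:
    def test_baseline_reduction(self):
        br = losses.total_objective(0.4, 0.3, 0.2, 0.9, 0.8,
                                    LossWeights(alpha=0, beta=0, lambda_cyc=10))
        assert br.total == pytest.approx(0.4 + 0.3 + 2.0)

    def test_default_weights_arithmetic(self):
        br = losses.total_objective(1.0, 0.0, 1.0, 1.0, 1.0, LossWeights())
        assert br.total == pytest.approx(14.05)

    def test_breakdown_fields_sum_to_total(self, rng):
        w = LossWeights(alpha=2.0, beta=0.1, lambda_cyc=5.0)
        parts = rng.random(5)
        br = losses.total_objective(*parts, w)
        recomputed = (br.adversarial_g + br.adversarial_f
                      + w.lambda_cyc * br.cycle + w.alpha * br.ic
                      + w.beta * br.dc)
        assert br.total == pytest.approx(recomputed)

    def test_nonfinite_component_named(self):
        with pytest.raises(ValueError, match="cycle"):
            losses.total_objective(0.0, 0.0, float("inf"), 0.0, 0.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(beta=-0.05)
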