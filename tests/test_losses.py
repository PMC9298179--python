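import numpy as np
import pytest

import oracles
from cellsharp import losses as L


class TestAdversarial:
    def test_perfect_discriminator_has_near_zero_loss(self):
        eps = L.EPS
        l_d, _ = L.adversarial_losses(np.full(4, 1 - eps), np.full(4, eps))
        assert l_d == pytest.approx(0.0, abs=1e-5)

    def test_coin_flip_fixed_points(self):
        for b in (1, 3, 16):
            l_d, l_g = L.adversarial_losses(np.full(b, 0.5), np.full(b, 0.5))
            assert l_d == pytest.approx(2 * np.log(2), rel=1e-12)
            assert l_g == pytest.approx(np.log(2), rel=1e-12)

    def test_winning_generator_loss_vanishes(self):
        _, l_g = L.adversarial_losses(np.full(2, 0.5), np.full(2, 1 - L.EPS))
        assert l_g == pytest.approx(0.0, abs=1e-5)

    def test_out_of_range_probabilities_clamped(self):
        l_d, l_g = L.adversarial_losses(np.array([1.0]), np.array([0.0]))
        assert np.isfinite(l_d) and np.isfinite(l_g)

    def test_matches_scalar_oracle(self, rng):
        dr, df = rng.uniform(0.05, 0.95, 5), rng.uniform(0.05, 0.95, 5)
        got = L.adversarial_losses(dr, df)
        want = oracles.adversarial_losses_loops(dr, df)
        assert got == pytest.approx(want, rel=1e-12)


class TestReconstruction:
    def test_identity_is_zero(self, fixture_batch):
        x, _ = fixture_batch
        assert L.reconstruction_loss(x, x) == 0.0

    def test_unit_difference(self):
        x = np.ones((1, 1, 2, 2))
        assert L.reconstruction_loss(x, np.zeros_like(x)) == pytest.approx(1.0)

    def test_quadratic_homogeneity(self, fixture_batch):
        x, xh = fixture_batch
        base = L.reconstruction_loss(x, xh)
        doubled = L.reconstruction_loss(x, x + 2 * (xh - x))
        assert doubled == pytest.approx(4 * base, rel=1e-12)

    def test_matches_scalar_oracle(self, fixture_batch):
        x, xh = fixture_batch
        assert L.reconstruction_loss(x, xh) == pytest.approx(
            oracles.rec_loss_loops(x, xh), rel=1e-10)

    def test_shape_mismatch_rejected(self, fixture_batch):
        x, _ = fixture_batch
        with pytest.raises(ValueError):
            L.reconstruction_loss(x, x[:, :, :8, :])


class TestTV:
    def test_constant_batch_is_zero(self):
        assert L.tv_loss(np.full((2, 1, 4, 4), 0.3)) == 0.0

    def test_hand_summation_example(self):
        # [0, 1, 0]: two unit column differences over B*C*H*W = 3
        x = np.array([0.0, 1.0, 0.0]).reshape(1, 1, 1, 3)
        with pytest.raises(ValueError):
            L.tv_loss(x)  # H < 2 is rejected...
        x2 = np.tile(x, (1, 1, 2, 1))  # ...so use two identical rows
        assert L.tv_loss(x2) == pytest.approx(4.0 / 6.0)

    def test_blur_decreases_tv(self, small_scene):
        from scipy import ndimage
        a = small_scene.pixels[None, None]
        b = ndimage.gaussian_filter(small_scene.pixels, 2.0)[None, None]
        assert L.tv_loss(b) < L.tv_loss(a)

    def test_matches_scalar_oracle(self, fixture_batch):
        _, xh = fixture_batch
        assert L.tv_loss(xh) == pytest.approx(oracles.tv_loss_loops(xh), rel=1e-10)


class TestGram:
    def test_identity_unfolding(self):
        f = np.zeros((2, 2, 2))
        f[0, 0, 0] = 1.0  # row 0 of the unfolding = e1
        f[1, 0, 1] = 1.0  # row 1 = e2
        assert np.allclose(L.gram(f), np.eye(2))

    def test_single_channel_is_sum_of_squares(self, rng):
        f = rng.normal(size=(1, 4, 4))
        assert L.gram(f)[0, 0] == pytest.approx(np.sum(f ** 2))

    def test_matches_triple_loop_oracle(self, rng):
        f = rng.normal(size=(3, 4, 4))
        assert np.allclose(L.gram(f), oracles.gram_loops(f), atol=1e-8)

    def test_symmetric_psd(self, rng):
        g = L.gram(rng.normal(size=(4, 5, 5)))
        assert np.allclose(g, g.T)
        assert np.min(np.linalg.eigvalsh(g)) >= -1e-10


class TestPerceptual:
    def test_identity_extractor_reduces_to_reconstruction(self, fixture_batch):
        x, xh = fixture_batch
        ide = L.IdentityExtractor()
        assert L.feature_loss(x, xh, ide) == pytest.approx(
            L.reconstruction_loss(x, xh), rel=1e-12)

    def test_zero_at_equality_any_extractor(self, fixture_batch):
        x, _ = fixture_batch
        for ex in (L.IdentityExtractor(), L.RandomConvExtractor(seed=3)):
            assert L.feature_loss(x, x, ex) == 0.0
            assert L.style_loss(x, x, ex) == 0.0

    def test_feature_loss_matches_loop_oracle(self, fixture_batch):
        x, xh = fixture_batch
        ex = L.RandomConvExtractor(seed=17)
        got = L.feature_loss(x, xh, ex)
        want = oracles.feature_loss_loops(ex.extract(x), ex.extract(xh))
        assert got == pytest.approx(want, rel=1e-6)

    def test_style_loss_matches_loop_oracle(self, fixture_batch):
        x, xh = fixture_batch
        ex = L.IdentityExtractor()
        got = L.style_loss(x, xh, ex)
        want = oracles.style_loss_loops(ex.extract(x), ex.extract(xh))
        assert got == pytest.approx(want, rel=1e-6)

    def test_style_blind_to_spatial_permutation(self, rng):
        """Gram discards layout: permuting pixels changes feature loss, not style."""
        x = rng.uniform(size=(1, 1, 4, 4))
        perm = rng.permutation(16)
        xp = x.reshape(1, 1, -1)[:, :, perm].reshape(x.shape)
        ide = L.IdentityExtractor()
        assert L.style_loss(x, xp, ide) == pytest.approx(0.0, abs=1e-12)
        assert L.feature_loss(x, xp, ide) > 0

    def test_batch_permutation_invariance(self, rng):
        x = rng.uniform(size=(4, 1, 8, 8))
        xh = rng.uniform(size=(4, 1, 8, 8))
        perm = rng.permutation(4)
        ex = L.RandomConvExtractor(seed=5)
        assert L.feature_loss(x, xh, ex) == pytest.approx(
            L.feature_loss(x[perm], xh[perm], ex), rel=1e-9)
        assert L.style_loss(x, xh, ex) == pytest.approx(
            L.style_loss(x[perm], xh[perm], ex), rel=1e-9)
        assert L.reconstruction_loss(x, xh) == pytest.approx(
            L.reconstruction_loss(x[perm], xh[perm]), rel=1e-12)

    def test_extractor_is_frozen(self, fixture_batch):
        x, _ = fixture_batch
        ex = L.RandomConvExtractor(seed=9)
        a = ex.extract(x)
        b = ex.extract(x)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa, fb)
        assert ex.descriptor.startswith("random-cnn-seed9")


class TestGeneratorTotal:
    def test_rec_only_weights(self, fixture_batch):
        x, xh = fixture_batch
        w = L.LossWeights(lambda_rec=1.0, lambda_feat=0.0, lambda_style=0.0,
                          lambda_tv=0.0, lambda_adv_g=0.0)
        rep = L.generator_total_loss(x, xh, None, L.IdentityExtractor(), w)
        assert rep.l_g_total == pytest.approx(L.reconstruction_loss(x, xh))

    def test_doubling_weights_doubles_total(self, fixture_batch):
        x, xh = fixture_batch
        ex = L.RandomConvExtractor(seed=2)
        d_fake = np.array([0.4, 0.6])
        w1 = L.LossWeights()
        w2 = L.LossWeights(lambda_rec=2 * w1.lambda_rec, lambda_feat=2 * w1.lambda_feat,
                           lambda_style=2 * w1.lambda_style, lambda_tv=2 * w1.lambda_tv,
                           lambda_adv_g=2 * w1.lambda_adv_g)
        r1 = L.generator_total_loss(x, xh, d_fake, ex, w1)
        r2 = L.generator_total_loss(x, xh, d_fake, ex, w2)
        assert r2.l_g_total == pytest.approx(2 * r1.l_g_total, rel=1e-9)

    def test_total_matches_componentwise_recomputation(self, fixture_batch):
        x, xh = fixture_batch
        ex = L.RandomConvExtractor(seed=17)
        w = L.LossWeights()
        d_fake = np.array([0.3, 0.7])
        rep = L.generator_total_loss(x, xh, d_fake, ex, w)
        expected = (w.lambda_rec * L.reconstruction_loss(x, xh)
                    + w.lambda_feat * L.feature_loss(x, xh, ex)
                    + w.lambda_style * L.style_loss(x, xh, ex)
                    + w.lambda_tv * L.tv_loss(xh)
                    + w.lambda_adv_g * rep.l_adv_g)
        assert rep.l_g_total == pytest.approx(expected, rel=1e-6)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            L.LossWeights(lambda_rec=-1.0)
        with pytest.raises(ValueError):
            L.LossWeights(lambda_rec=0, lambda_feat=0, lambda_style=0,
                          lambda_tv=0, lambda_adv_g=0)
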