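import numpy as np
import pytest

from cellsharp import nn
from cellsharp.image_io import ImageBatch
from cellsharp.model import (Discriminator, DiscriminatorConfig, Generator,
                             GeneratorConfig, weight_shapes)


def finite_difference_input_grad(module, x, upstream, eps=1e-2):
    def loss(xx):
        return float(np.sum(upstream * module.forward(xx)))
    module.zero_grad()
    module.forward(x)
    analytic = module.backward(upstream)
    rng = np.random.default_rng(0)
    errs = []
    for _ in range(6):
        i = tuple(rng.integers(0, s) for s in x.shape)
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        num = (loss(xp) - loss(xm)) / (2 * eps)
        errs.append(abs(num - analytic[i]) / (abs(num) + 1e-4))
    return max(errs)


class TestLayers:
    @pytest.mark.parametrize("layer_fn", [
        lambda r: nn.Conv2d(3, 4, 3, rng=r, init_std=0.2),
        lambda r: nn.Conv2d(3, 4, 3, stride=2, rng=r, init_std=0.2),
        lambda r: nn.ConvTranspose2d(3, 4, 4, stride=2, pad=1, rng=r, init_std=0.2),
        lambda r: nn.Residual(3, r),
    ], ids=["conv_s1", "conv_s2", "convT_s2", "residual"])
    def test_input_gradients_match_finite_differences(self, layer_fn, rng):
        layer = layer_fn(np.random.default_rng(7))
        x = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
        upstream = rng.normal(size=layer.forward(x).shape).astype(np.float32)
        assert finite_difference_input_grad(layer, x, upstream) < 0.05

    def test_param_gradients_match_finite_differences(self, rng):
        layer = nn.Conv2d(2, 3, 3, stride=2, rng=np.random.default_rng(3), init_std=0.3)
        x = rng.normal(size=(2, 2, 8, 8)).astype(np.float32)
        upstream = rng.normal(size=layer.forward(x).shape).astype(np.float32)

        def loss():
            return float(np.sum(upstream * layer.forward(x)))
        layer.zero_grad()
        layer.forward(x)
        layer.backward(upstream)
        eps = 1e-2
        for p in layer.params():
            flat, grad = p.value.reshape(-1), p.grad.reshape(-1)
            j = rng.integers(0, flat.size)
            orig = flat[j]
            flat[j] = orig + eps
            lp = loss()
            flat[j] = orig - eps
            lm = loss()
            flat[j] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - grad[j]) / (abs(num) + 1e-3) < 0.05

    def test_conv_transpose_doubles_spatial_size(self):
        layer = nn.ConvTranspose2d(2, 2, 4, stride=2, pad=1)
        y = layer.forward(np.zeros((1, 2, 8, 8), dtype=np.float32))
        assert y.shape == (1, 2, 16, 16)

    def test_adam_state_roundtrip(self, rng):
        p = nn.Param(rng.normal(size=(3, 3)))
        opt = nn.Adam([p])
        p.grad[...] = 1.0
        opt.step()
        st = opt.state()
        opt2 = nn.Adam([nn.Param(p.value.copy())])
        opt2.load_state(st)
        assert opt2.t == opt.t
        assert np.array_equal(opt2.m[0], opt.m[0])


class TestGenerator:
    def test_shape_and_range_contract(self):
        g = Generator(GeneratorConfig(base_channels=8, n_down=2, n_residual=1), seed=1)
        x = np.random.default_rng(0).uniform(size=(2, 1, 64, 64))
        y = g.forward(x)
        assert y.shape == (2, 1, 64, 64)
        assert np.all((y >= 0) & (y <= 1))

    def test_deterministic_forward(self):
        g = Generator(GeneratorConfig(base_channels=8, n_down=2, n_residual=1), seed=1)
        x = np.random.default_rng(0).uniform(size=(1, 1, 32, 32))
        assert np.array_equal(g.forward(x), g.forward(x))

    def test_seeded_init_reproducible(self):
        a = Generator(GeneratorConfig(base_channels=8), seed=5)
        b = Generator(GeneratorConfig(base_channels=8), seed=5)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_incompatible_size_names_constraint(self):
        g = Generator(GeneratorConfig(n_down=3), seed=0)
        with pytest.raises(ValueError, match="2\\*\\*n_down"):
            g.forward(np.zeros((1, 1, 60, 60)))

    def test_output_closed_under_composition(self):
        g = Generator(GeneratorConfig(base_channels=8, n_down=2, n_residual=1), seed=2)
        x = np.random.default_rng(1).uniform(size=(1, 1, 32, 32))
        y = g.forward(g.forward(x))
        assert np.all((y >= 0) & (y <= 1))

    def test_identity_mapping_sanity(self):
        """The logit-residual head makes an untrained generator near-identity,
        and short supervised training on identity pairs keeps the pixel loss
        far below the image-variance scale instead of diverging."""
        from cellsharp import losses as L
        from cellsharp.synthetic_cells import SceneSpec, synth_sharp_image
        rng = np.random.default_rng(3)
        imgs = [synth_sharp_image(SceneSpec(image_size=32, n_cells=3,
                                            cell_radius_range=(3.0, 6.0), seed=s)).pixels
                for s in range(32)]
        x = np.stack(imgs)[:, None].astype(np.float32)
        g = Generator(GeneratorConfig(base_channels=8, n_down=2, n_residual=1), seed=4)
        initial = L.reconstruction_loss(x, g.forward(x))
        assert initial < 1e-6  # identity at initialisation
        opt = nn.Adam(g.params())
        for _ in range(300):
            idx = rng.choice(32, size=8, replace=False)
            xb = x[idx]
            xh = g.forward(xb)
            _, dxh = L.reconstruction_grad(xb, xh)
            g.zero_grad()
            g.backward(dxh.astype(np.float32))
            opt.step()
        final = L.reconstruction_loss(x, g.forward(x))
        variance_scale = float(np.var(x))
        assert final < 0.01 * variance_scale

    def test_no_fully_connected_layers(self):
        g = Generator(GeneratorConfig(), seed=0)
        for shape in weight_shapes(g):
            assert len(shape) in (1, 4)  # conv kernels and biases only


class TestDiscriminator:
    def test_probability_per_item(self):
        d = Discriminator(DiscriminatorConfig(base_channels=8, n_down=2), seed=1)
        p = d.forward(np.random.default_rng(0).uniform(size=(5, 1, 64, 64)))
        assert p.shape == (5,)
        assert np.all((p > 0) & (p < 1))

    def test_deterministic(self):
        d = Discriminator(DiscriminatorConfig(base_channels=8, n_down=2), seed=1)
        x = np.random.default_rng(0).uniform(size=(2, 1, 32, 32))
        assert np.array_equal(d.forward(x), d.forward(x))

    def test_only_conv_weights(self):
        d = Discriminator(DiscriminatorConfig(), seed=0)
        for shape in weight_shapes(d):
            assert len(shape) in (1, 4)
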