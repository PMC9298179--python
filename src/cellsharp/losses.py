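"""The combined GAN training objective: adversarial, pixel, perceptual, TV.

The generator objective is a weighted sum

    L_G = l_rec * L_rec + l_feat * L_feat + l_style * L_style
          + l_tv * L_tv + l_adv * L_advG

with L_rec the mean squared pixel error, L_feat / L_style perceptual
distances over the feature maps (and their Gram matrices) of a frozen
convolutional extractor, L_tv the squared total-variation regulariser and
L_advG the non-saturating adversarial term.  The discriminator minimises the
standard cross-entropy L_advD = -mean[log D(x) + log(1 - D(x_hat))].

Each public function returns the scalar loss; the ``*_grad`` variants also
return the gradient with respect to the generated batch, which is what the
training loop feeds back through the generator.

The canonical perceptual extractor in the literature is an ImageNet
pre-trained VGG; this package defaults to a frozen, seed-fixed random
convolutional extractor with the same tap structure so that everything runs
without downloaded weights.  Random deep features are a known usable
perceptual basis; the extractor provenance travels in ``descriptor``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "EPS", "LossWeights", "LossReport", "FeatureExtractor", "IdentityExtractor",
    "RandomConvExtractor", "adversarial_losses", "reconstruction_loss", "gram",
    "feature_loss", "style_loss", "tv_loss", "generator_total_loss",
]

#: probabilities are clamped to [EPS, 1-EPS] before any log
EPS = 1e-7


@dataclass
class LossWeights:
    """λ coefficients of the generator objective (all >= 0, not all zero)."""

    lambda_rec: float = 1.0
    lambda_feat: float = 0.05
    lambda_style: float = 1e-4
    lambda_tv: float = 1e-4
    lambda_adv_g: float = 1e-3

    def __post_init__(self) -> None:
        vals = (self.lambda_rec, self.lambda_feat, self.lambda_style,
                self.lambda_tv, self.lambda_adv_g)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be >= 0")
        if not any(v > 0 for v in vals):
            raise ValueError("at least one loss weight must be > 0")


@dataclass
class LossReport:
    l_rec: float = 0.0
    l_feat: float = 0.0
    l_style: float = 0.0
    l_tv: float = 0.0
    l_adv_g: float = 0.0
    l_adv_d: float = 0.0
    l_g_total: float = 0.0


def _as_array(batch) -> np.ndarray:
    data = getattr(batch, "data", batch)
    return np.asarray(data, dtype=np.float64)


# ---------------------------------------------------------------- adversarial

def adversarial_losses(d_real: np.ndarray, d_fake: np.ndarray) -> tuple[float, float]:
    """Minimisation-form adversarial losses of discriminator and generator.

    ``l_adv_d = -mean[log d_real + log(1 - d_fake)]`` (the negated
    discriminator maximisation) and ``l_adv_g = -mean[log d_fake]`` (the
    non-saturating generator form, whose optimum coincides with minimising
    ``log(1 - D(x_hat))`` but whose gradient does not vanish early).
    """
    dr = np.clip(np.asarray(d_real, dtype=np.float64), EPS, 1 - EPS)
    df = np.clip(np.asarray(d_fake, dtype=np.float64), EPS, 1 - EPS)
    l_adv_d = float(-np.mean(np.log(dr) + np.log(1.0 - df)))
    l_adv_g = float(-np.mean(np.log(df)))
    return l_adv_d, l_adv_g


def adversarial_grads(d_real: np.ndarray, d_fake: np.ndarray):
    """d(l_adv_d)/d(d_real), d(l_adv_d)/d(d_fake) and d(l_adv_g)/d(d_fake)."""
    dr = np.clip(np.asarray(d_real, dtype=np.float64), EPS, 1 - EPS)
    df = np.clip(np.asarray(d_fake, dtype=np.float64), EPS, 1 - EPS)
    return (-1.0 / (dr.size * dr), 1.0 / (df.size * (1.0 - df)),
            -1.0 / (df.size * df))


# -------------------------------------------------------------- pixel / tv

def reconstruction_loss(x, x_hat) -> float:
    """Mean squared pixel error: ||x - x_hat||^2 / (B*C*H*W)."""
    a, b = _as_array(x), _as_array(x_hat)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def reconstruction_grad(x, x_hat) -> tuple[float, np.ndarray]:
    a, b = _as_array(x), _as_array(x_hat)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    diff = b - a
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size


def tv_loss(x_hat) -> float:
    """Squared total variation, rows and columns separately, over B*C*H*W."""
    a = _as_array(x_hat)
    if a.shape[2] < 2 or a.shape[3] < 2:
        raise ValueError("tv_loss needs H >= 2 and W >= 2")
    dh = np.diff(a, axis=2)
    dw = np.diff(a, axis=3)
    return float((np.sum(dh ** 2) + np.sum(dw ** 2)) / a.size)


def tv_grad(x_hat) -> tuple[float, np.ndarray]:
    a = _as_array(x_hat)
    if a.shape[2] < 2 or a.shape[3] < 2:
        raise ValueError("tv_loss needs H >= 2 and W >= 2")
    dh = np.diff(a, axis=2)
    dw = np.diff(a, axis=3)
    loss = (np.sum(dh ** 2) + np.sum(dw ** 2)) / a.size
    g = np.zeros_like(a)
    g[:, :, 1:, :] += 2.0 * dh
    g[:, :, :-1, :] -= 2.0 * dh
    g[:, :, :, 1:] += 2.0 * dw
    g[:, :, :, :-1] -= 2.0 * dw
    return float(loss), g / a.size


# ------------------------------------------------------------- perceptual

class FeatureExtractor:
    """Frozen map from a batch to an ordered list of feature tensors Φ_i."""

    descriptor: str = "abstract"

    def extract(self, x: np.ndarray) -> list[np.ndarray]:  # pragma: no cover
        raise NotImplementedError

    def backprop(self, x: np.ndarray, tap_grads: list[np.ndarray]) -> np.ndarray:
        """Gradient w.r.t. ``x`` of sum_i <tap_grads[i], Φ_i(x)>."""
        raise NotImplementedError  # pragma: no cover


class IdentityExtractor(FeatureExtractor):
    """Single-layer Φ = identity; reduces feature loss to pixel loss."""

    descriptor = "identity"

    def extract(self, x: np.ndarray) -> list[np.ndarray]:
        return [np.asarray(x, dtype=np.float64)]

    def backprop(self, x: np.ndarray, tap_grads: list[np.ndarray]) -> np.ndarray:
        return np.asarray(tap_grads[0], dtype=np.float64)


class RandomConvExtractor(FeatureExtractor):
    """Frozen random CNN with one ReLU tap per conv block.

    Expects 3-channel input (single-channel batches are replicated), matching
    the convention of ImageNet-style perceptual extractors.
    """

    def __init__(self, seed: int = 17, widths: tuple[int, ...] = (8, 16, 16),
                 strides: tuple[int, ...] = (1, 2, 2)):
        if len(widths) != len(strides):
            raise ValueError("widths and strides must have equal length")
        rng = np.random.default_rng(seed)
        self.blocks: list[nn.Sequential] = []
        cin = 3
        for wdt, s in zip(widths, strides):
            self.blocks.append(nn.Sequential([
                nn.Conv2d(cin, wdt, 3, stride=s, rng=rng, init_std=0.2),
                nn.ReLU(),
            ]))
            cin = wdt
        self.descriptor = f"random-cnn-seed{seed}-w{'x'.join(map(str, widths))}"

    @staticmethod
    def _to_rgb(x: np.ndarray) -> tuple[np.ndarray, bool]:
        x = np.asarray(x, dtype=np.float64)
        if x.shape[1] == 1:
            return np.repeat(x, 3, axis=1), True
        if x.shape[1] == 3:
            return x, False
        raise ValueError(f"extractor expects 1 or 3 channels, got {x.shape[1]}")

    def extract(self, x: np.ndarray) -> list[np.ndarray]:
        h, _ = self._to_rgb(x)
        taps = []
        for block in self.blocks:
            h = block.forward(h)
            taps.append(h.astype(np.float64))
        return taps

    def backprop(self, x: np.ndarray, tap_grads: list[np.ndarray]) -> np.ndarray:
        h, replicated = self._to_rgb(x)
        for block in self.blocks:  # repopulate forward caches
            h = block.forward(h)
        grad = np.zeros_like(tap_grads[-1])
        for block, g in zip(reversed(self.blocks), reversed(tap_grads)):
            grad = block.backward((grad + g).astype(nn.DTYPE))
        grad = np.asarray(grad, dtype=np.float64)
        if replicated:
            grad = grad.sum(axis=1, keepdims=True)
        return grad


def gram(features: np.ndarray) -> np.ndarray:
    """Gram = A A^T of the C x (H*W) unfolding of one C x H x W feature map."""
    f = np.asarray(features, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError(f"gram expects a C x H x W map, got ndim={f.ndim}")
    a = f.reshape(f.shape[0], -1)
    return a @ a.T


def _layer_norms(taps: list[np.ndarray]) -> list[float]:
    return [float(np.prod(t.shape)) for t in taps]


def feature_loss(x, x_hat, extractor: FeatureExtractor) -> float:
    """Sum over taps of ||Φ_i(x) - Φ_i(x_hat)||^2 / (B*C_i*H_i*W_i)."""
    a, b = _as_array(x), _as_array(x_hat)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    ta, tb = extractor.extract(a), extractor.extract(b)
    return float(sum(np.sum((fa - fb) ** 2) / fa.size for fa, fb in zip(ta, tb)))


def feature_grad(x, x_hat, extractor: FeatureExtractor) -> tuple[float, np.ndarray]:
    a, b = _as_array(x), _as_array(x_hat)
    ta, tb = extractor.extract(a), extractor.extract(b)
    loss = 0.0
    tap_grads = []
    for fa, fb in zip(ta, tb):
        diff = fb - fa
        loss += np.sum(diff ** 2) / fa.size
        tap_grads.append(2.0 * diff / fa.size)
    return float(loss), extractor.backprop(b, tap_grads)


def style_loss(x, x_hat, extractor: FeatureExtractor,
               normalize_gram: bool = False) -> float:
    """Sum over taps of ||Gram_i(x) - Gram_i(x_hat)||_F^2 / (B*C_i*H_i*W_i).

    Gram matrices are computed per batch item and the squared Frobenius
    distances summed over the batch; the normaliser is the feature-tensor
    element count, exactly as the objective is printed (no per-Gram 1/(CHW)
    scaling — see ``normalize_gram`` for the conventional variant).
    """
    return _style_impl(x, x_hat, extractor, want_grad=False,
                       normalize_gram=normalize_gram)[0]


def style_grad(x, x_hat, extractor: FeatureExtractor,
               normalize_gram: bool = False) -> tuple[float, np.ndarray]:
    return _style_impl(x, x_hat, extractor, want_grad=True,
                       normalize_gram=normalize_gram)


def _style_impl(x, x_hat, extractor: FeatureExtractor, want_grad: bool,
                normalize_gram: bool = False):
    a, b = _as_array(x), _as_array(x_hat)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    ta, tb = extractor.extract(a), extractor.extract(b)
    loss = 0.0
    tap_grads = []
    for fa, fb in zip(ta, tb):
        bsz, c = fa.shape[0], fa.shape[1]
        scale = 1.0 / fa.size
        gram_scale = 1.0 / (c * fa.shape[2] * fa.shape[3]) if normalize_gram else 1.0
        g_tap = np.zeros_like(fb)
        for i in range(bsz):
            aa = fa[i].reshape(c, -1)
            bb = fb[i].reshape(c, -1)
            delta = (bb @ bb.T - aa @ aa.T) * gram_scale
            loss += scale * np.sum(delta ** 2)
            if want_grad:
                # d||Δ||²/dB = 4 Δ B   (Δ symmetric)
                g_tap[i] = (4.0 * scale * gram_scale * (delta @ bb)).reshape(fb[i].shape)
        tap_grads.append(g_tap)
    if not want_grad:
        return float(loss), None
    return float(loss), extractor.backprop(b, tap_grads)


# ----------------------------------------------------------------- combined

def generator_total_loss(x, x_hat, d_fake, extractor: FeatureExtractor,
                         weights: LossWeights, d_real=None) -> LossReport:
    """All generator loss terms plus the λ-weighted total, for logging."""
    l_rec = reconstruction_loss(x, x_hat)
    l_feat = feature_loss(x, x_hat, extractor) if weights.lambda_feat > 0 else 0.0
    l_style = style_loss(x, x_hat, extractor) if weights.lambda_style > 0 else 0.0
    l_tv = tv_loss(x_hat)
    if d_fake is not None:
        l_adv_d, l_adv_g = adversarial_losses(
            d_real if d_real is not None else np.array([1.0 - EPS]), d_fake)
        if d_real is None:
            l_adv_d = 0.0
    else:
        l_adv_d = l_adv_g = 0.0
    total = (weights.lambda_rec * l_rec + weights.lambda_feat * l_feat
             + weights.lambda_style * l_style + weights.lambda_tv * l_tv
             + weights.lambda_adv_g * l_adv_g)
    return LossReport(l_rec=l_rec, l_feat=l_feat, l_style=l_style, l_tv=l_tv,
                      l_adv_g=l_adv_g, l_adv_d=l_adv_d, l_g_total=float(total))
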