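"""Enhancement GAN networks: encoder-decoder generator and conv discriminator.

The generator maps a blurred image batch to an enhanced one of the same
shape: a conv stem, ``n_down`` stride-2 downsampling convs into a latent
representation, ``n_residual`` residual blocks, mirrored transposed-conv
upsampling, and a 1x1 conv head.  The head predicts a *logit residual*: the
output is ``sigmoid(head + logit(input))``, so a freshly initialised
generator is (near-)identity and training learns the sharpening correction.
This global residual is a single input-to-output shortcut in the spirit of
super-resolution generators; the decoder itself has no per-scale skips.

The discriminator is all-convolutional (DCGAN convention — no fully
connected layers): stride-2 leaky-ReLU convs, a 1-channel conv head, global
average and a sigmoid producing one real/fake probability per image.

No canonical layer counts or widths exist for this task; this architecture
is a deliberately small, faithful-genre stand-in sized so that training runs
on one CPU (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .image_io import ImageBatch

__all__ = ["GeneratorConfig", "DiscriminatorConfig", "Generator", "Discriminator"]


@dataclass(frozen=True)
class GeneratorConfig:
    base_channels: int = 16
    n_down: int = 2
    n_residual: int = 3
    in_channels: int = 1
    out_channels: int = 1

    def validate_size(self, h: int, w: int) -> None:
        d = 2 ** self.n_down
        if h % d or w % d:
            raise ValueError(
                f"generator input {h}x{w} violates the divisibility constraint: "
                f"height and width must be multiples of 2**n_down = {d}")


@dataclass(frozen=True)
class DiscriminatorConfig:
    base_channels: int = 16
    n_down: int = 3
    in_channels: int = 1
    spectral_norm: bool = False  # reserved; not used by the small CPU nets


class Generator(nn.Module):
    def __init__(self, config: GeneratorConfig = GeneratorConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.base_channels
        layers: list[nn.Module] = [nn.Conv2d(config.in_channels, c, 3, rng=rng), nn.LeakyReLU()]
        ch = c
        for _ in range(config.n_down):
            layers += [nn.Conv2d(ch, ch * 2, 3, stride=2, rng=rng), nn.LeakyReLU()]
            ch *= 2
        for _ in range(config.n_residual):
            layers.append(nn.Residual(ch, rng))
        for _ in range(config.n_down):
            layers += [nn.ConvTranspose2d(ch, ch // 2, 4, stride=2, pad=1, rng=rng),
                       nn.LeakyReLU()]
            ch //= 2
        layers.append(nn.Conv2d(ch, config.out_channels, 1, rng=rng))
        self.net = nn.Sequential(layers)
        self.sigmoid = nn.Sigmoid()
        self._logit_eps = 1e-4
        self._cache_x = None

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=nn.DTYPE)
        self.config.validate_size(x.shape[2], x.shape[3])
        xc = np.clip(x, self._logit_eps, 1.0 - self._logit_eps)
        if self.config.in_channels == self.config.out_channels:
            skip = np.log(xc / (1.0 - xc))
        else:  # channel-changing variant has no natural identity path
            skip = 0.0
        self._cache_x = xc
        return self.sigmoid.forward(self.net.forward(x) + skip)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = self.sigmoid.backward(np.asarray(dy, dtype=nn.DTYPE))
        dx = self.net.backward(dz)
        if self.config.in_channels == self.config.out_channels:
            xc = self._cache_x
            dx = dx + dz / (xc * (1.0 - xc))
        return dx

    def enhance(self, batch: ImageBatch) -> ImageBatch:
        """Forward pass on an ImageBatch, returned as float64 ImageBatch."""
        return ImageBatch(self.forward(batch.data).astype(np.float64))


class Discriminator(nn.Module):
    def __init__(self, config: DiscriminatorConfig = DiscriminatorConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.base_channels
        layers: list[nn.Module] = [nn.Conv2d(config.in_channels, c, 3, stride=2, rng=rng),
                                   nn.LeakyReLU()]
        ch = c
        for _ in range(config.n_down - 1):
            layers += [nn.Conv2d(ch, ch * 2, 3, stride=2, rng=rng), nn.LeakyReLU()]
            ch *= 2
        layers.append(nn.Conv2d(ch, 1, 3, rng=rng))  # 1-channel conv head
        self.net = nn.Sequential(layers)
        self.sigmoid = nn.Sigmoid()
        self._spatial = None

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Return one probability in (0, 1) per batch item."""
        score_map = self.net.forward(np.asarray(x, dtype=nn.DTYPE))
        self._spatial = score_map.shape
        score = score_map.mean(axis=(1, 2, 3))
        return self.sigmoid.forward(score)

    def backward(self, dprob: np.ndarray) -> np.ndarray:
        dscore = self.sigmoid.backward(np.asarray(dprob, dtype=nn.DTYPE))
        b, c, h, w = self._spatial
        dmap = np.broadcast_to(dscore[:, None, None, None], self._spatial) / (c * h * w)
        return self.net.backward(np.ascontiguousarray(dmap, dtype=nn.DTYPE))


def weight_shapes(module: nn.Module) -> list[tuple[int, ...]]:
    """Shapes of all learnable tensors; used to assert the no-FC-layer convention."""
    return [p.value.shape for p in module.params()]
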