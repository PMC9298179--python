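"""Classic enhancement baseline: unsharp masking composed with CLAHE.

This is both the traditional-enhancement (TE) comparison arm and the
producer of enhanced-ground-truth (EGT) targets: applying the same pipeline
to a ground-truth image yields the EGT used to train the "plus" variant of
the GAN.  Unsharp masking sharpens (adds back a scaled high-pass), CLAHE
stretches local contrast with a clipped per-tile histogram equalisation.
The pipeline is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure

from .image_io import ImageGrid

__all__ = ["EnhanceParams", "unsharp_mask", "clahe", "traditional_enhance"]


@dataclass(frozen=True)
class EnhanceParams:
    """Common-practice defaults; there are no canonical values for this task."""

    unsharp_radius: float = 2.0
    unsharp_amount: float = 1.0
    clahe_clip_limit: float = 0.01
    clahe_tiles: int = 8

    def __post_init__(self) -> None:
        if self.unsharp_radius <= 0:
            raise ValueError("unsharp_radius must be > 0")
        if self.unsharp_amount < 0:
            raise ValueError("unsharp_amount must be >= 0")
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be > 0")
        if self.clahe_tiles < 1:
            raise ValueError("clahe_tiles must be >= 1")


def _like(grid: ImageGrid, pixels: np.ndarray) -> ImageGrid:
    return ImageGrid(pixels, pixel_size=grid.pixel_size,
                     bit_depth_origin=grid.bit_depth_origin)


def unsharp_mask(img: ImageGrid, radius: float, amount: float) -> ImageGrid:
    """out = clamp(img + amount * (img - gaussian_blur(img, radius)))."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if amount < 0:
        raise ValueError("amount must be >= 0")
    px = img.pixels
    high_pass = px - ndimage.gaussian_filter(px, radius, mode="reflect")
    return _like(img, np.clip(px + amount * high_pass, 0.0, 1.0))


def clahe(img: ImageGrid, clip_limit: float, tiles: int) -> ImageGrid:
    """Contrast-limited adaptive histogram equalisation on the [0, 1] raster.

    ``tiles`` is the tile count per image side; if the image is smaller than
    the tile grid the count is reduced with a warning.
    """
    if clip_limit <= 0 or tiles < 1:
        raise ValueError("clip_limit must be > 0 and tiles >= 1")
    h, w = img.pixels.shape
    min_side = min(h, w)
    if min_side // tiles < 1:
        new_tiles = max(1, min_side)
        warnings.warn(f"image {h}x{w} smaller than {tiles}x{tiles} tile grid; "
                      f"reducing to {new_tiles}", stacklevel=2)
        tiles = new_tiles
    px = img.pixels
    if px.max() == px.min():
        return _like(img, px.copy())  # degenerate mapping: leave constant images alone
    kernel = (max(1, h // tiles), max(1, w // tiles))
    out = exposure.equalize_adapthist(np.clip(px, 0.0, 1.0), kernel_size=kernel,
                                      clip_limit=clip_limit, nbins=256)
    return _like(img, out)


def traditional_enhance(img: ImageGrid, params: EnhanceParams = EnhanceParams()) -> ImageGrid:
    """TE pipeline: sharpen first (unsharp mask), then contrast (CLAHE)."""
    sharpened = unsharp_mask(img, params.unsharp_radius, params.unsharp_amount)
    out = clahe(sharpened, params.clahe_clip_limit, params.clahe_tiles)
    out.meta["enhance_params"] = params
    return out
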