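"""Reading, writing and normalising microscopy rasters.

All internal computation happens on float intensities in [0, 1].  Images on
disk are 8- or 16-bit PNG/TIFF; loading divides by the integer maximum of the
source bit depth, writing re-quantises.  RGB frames are collapsed to Rec. 601
luminance because brightfield and single-stain fluorescence data are
effectively single-channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "ImageGrid",
    "ImageBatch",
    "FormatError",
    "read_image",
    "write_image",
    "to_batch",
    "batch_to_grids",
    "DEFAULT_PIXEL_SIZE_UM",
]

#: camera pixel pitch of the acquisition setup emulated throughout: 0.65 um/px
DEFAULT_PIXEL_SIZE_UM = 0.65

_REC601 = np.array([0.299, 0.587, 0.114])


class FormatError(ValueError):
    """Raised for files that are not readable 8/16-bit PNG or TIFF rasters."""


@dataclass
class ImageGrid:
    """A single 2-D intensity raster in [0, 1] with physical pixel size."""

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    bit_depth_origin: int = 8
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"ImageGrid needs a 2-D array, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ImageGrid intensities must be finite")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def clipped(self) -> "ImageGrid":
        """Copy with intensities clamped to [0, 1]."""
        return ImageGrid(np.clip(self.pixels, 0.0, 1.0), self.pixel_size,
                         self.bit_depth_origin, dict(self.meta))


@dataclass
class ImageBatch:
    """B x C x H x W stack — the unit flowing through networks and losses."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"ImageBatch needs a 4-D array, got ndim={self.data.ndim}")
        b, c, _, _ = self.data.shape
        if b < 1 or c not in (1, 3):
            raise ValueError(f"ImageBatch needs B >= 1 and C in {{1, 3}}, got B={b}, C={c}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageBatch entries must be finite")

    @property
    def B(self) -> int:
        return self.data.shape[0]

    @property
    def C(self) -> int:
        return self.data.shape[1]

    @property
    def H(self) -> int:
        return self.data.shape[2]

    @property
    def W(self) -> int:
        return self.data.shape[3]


def _luminance(arr: np.ndarray) -> np.ndarray:
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return arr @ _REC601


def read_image(path: str | Path, pixel_size: float = DEFAULT_PIXEL_SIZE_UM) -> ImageGrid:
    """Load a PNG or TIFF raster, normalise to float [0, 1].

    Integer images are divided by ``2**bit_depth - 1``; float images are
    assumed already normalised.  RGB(A) is collapsed to luminance.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix not in {".png", ".tif", ".tiff"}:
        raise FormatError(f"unsupported format {suffix!r}; only PNG and TIFF are readable")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - codec specific
        raise FormatError(f"unreadable image {path}: {exc}") from exc
    src_dtype = arr.dtype

    if arr.ndim == 3:
        if arr.shape[-1] not in (3, 4):
            raise FormatError(f"unsupported channel layout {arr.shape} in {path}")
        arr = _luminance(arr.astype(np.float64))
        # luminance of integers is float but still on the integer scale
    elif arr.ndim != 2:
        raise FormatError(f"unsupported array shape {arr.shape} in {path}")

    if np.issubdtype(src_dtype, np.integer):
        bit_depth = 16 if src_dtype.itemsize >= 2 else 8
        arr = np.asarray(arr, dtype=np.float64) / float(2 ** bit_depth - 1)
    else:
        bit_depth = 8
        arr = np.clip(np.asarray(arr, dtype=np.float64), 0.0, 1.0)

    if arr.size and arr.min() == arr.max() and arr.max() in (0.0, 1.0):
        warnings.warn(f"{path.name}: image is constant and saturated", stacklevel=2)
    return ImageGrid(arr, pixel_size=pixel_size, bit_depth_origin=bit_depth)


def write_image(grid: ImageGrid, path: str | Path, bit_depth: int = 8) -> Path:
    """Quantise to ``bit_depth`` and write PNG or TIFF (chosen by suffix)."""
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    path = Path(path)
    px = grid.pixels
    if px.min() < 0.0 or px.max() > 1.0:
        warnings.warn(f"{path.name}: intensities outside [0, 1] clamped on write",
                      stacklevel=2)
        px = np.clip(px, 0.0, 1.0)
    maxv = 2 ** bit_depth - 1
    quant = np.round(px * maxv).astype(np.uint8 if bit_depth == 8 else np.uint16)
    suffix = path.suffix.lower()
    if suffix == ".png":
        iio.imwrite(path, quant)
    elif suffix in {".tif", ".tiff"}:
        tifffile.imwrite(path, quant)
    else:
        raise FormatError(f"unsupported output format {suffix!r}")
    return path


def to_batch(grids: list[ImageGrid], channels: int = 1) -> ImageBatch:
    """Stack shape-matched grids into a batch; C=3 replicates the gray plane."""
    if channels not in (1, 3):
        raise ValueError(f"channels must be 1 or 3, got {channels}")
    if not grids:
        raise ValueError("cannot build an ImageBatch from an empty list")
    shapes = {g.pixels.shape for g in grids}
    if len(shapes) != 1:
        raise ValueError(f"heterogeneous grid shapes: {sorted(shapes)}")
    stack = np.stack([g.pixels for g in grids])[:, None, :, :]
    if channels == 3:
        stack = np.repeat(stack, 3, axis=1)
    return ImageBatch(stack)


def batch_to_grids(batch: ImageBatch, pixel_size: float = DEFAULT_PIXEL_SIZE_UM) -> list[ImageGrid]:
    """Inverse of :func:`to_batch`; multi-channel batches are averaged to gray."""
    data = batch.data.mean(axis=1) if batch.C > 1 else batch.data[:, 0]
    return [ImageGrid(np.clip(frame, 0.0, 1.0), pixel_size=pixel_size) for frame in data]
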