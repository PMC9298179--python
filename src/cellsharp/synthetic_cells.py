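"""Synthetic cell-like scenes and their paired degradations.

Emulates the features of long-term live-cell brightfield imaging that drive
the enhancement task: monolayers of textured elliptical cells that tend to
cluster, small dark dead-cell debris, uneven illumination — degraded by
defocus (Gaussian blur), brightness/contrast attenuation and sensor noise.
Two paired-data sources are modelled: simulated defocus Z-stacks (blur
growing with distance from the focal plane) and direct Gaussian-blur
degradation of a sharp frame.

Every output is a pure function of its spec and seed, so datasets are
reproducible end-to-end from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image_io import DEFAULT_PIXEL_SIZE_UM, ImageGrid

__all__ = [
    "SceneSpec", "DegradationSpec", "DegradationRanges", "PairedDataset",
    "ZStack", "synth_sharp_image", "simulate_z_stack", "degrade",
    "build_dataset", "BLUR_SIGMA_PER_UM_DEFOCUS",
]

#: defocus-to-blur mapping: sigma_px = slope * |dz| um / pixel_size
BLUR_SIGMA_PER_UM_DEFOCUS = 0.15


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one sharp synthetic field of view."""

    image_size: int = 256
    n_cells: int = 25
    cell_radius_range: tuple[float, float] = (6.0, 14.0)
    cluster_probability: float = 0.6
    dead_cell_dot_rate: float = 3.0
    illumination_gradient: float = 0.1
    texture_amplitude: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cell_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("cell_radius_range must be positive with min <= max")
        for name in ("cluster_probability",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.illumination_gradient <= 0.5:
            raise ValueError("illumination_gradient must be in [0, 0.5]")
        if not 0.0 <= self.texture_amplitude <= 0.5:
            raise ValueError("texture_amplitude must be in [0, 0.5]")


@dataclass(frozen=True)
class DegradationSpec:
    """One deterministic degradation: blur -> contrast/brightness -> noise."""

    blur_sigma: float = 2.0
    noise_sigma: float = 0.01
    brightness_scale: float = 1.0
    contrast_scale: float = 1.0
    z_offset_layers: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if not 0.0 <= self.noise_sigma <= 0.2:
            raise ValueError("noise_sigma must be in [0, 0.2]")
        for name in ("brightness_scale", "contrast_scale"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class DegradationRanges:
    """Uniform sampling ranges used by :func:`build_dataset`."""

    blur_sigma: tuple[float, float] = (1.0, 3.0)
    noise_sigma: tuple[float, float] = (0.0, 0.02)
    brightness_scale: tuple[float, float] = (0.85, 1.0)
    contrast_scale: tuple[float, float] = (0.8, 1.0)

    def sample(self, rng: np.random.Generator, seed: int) -> DegradationSpec:
        return DegradationSpec(
            blur_sigma=float(rng.uniform(*self.blur_sigma)),
            noise_sigma=float(rng.uniform(*self.noise_sigma)),
            brightness_scale=float(rng.uniform(*self.brightness_scale)),
            contrast_scale=float(rng.uniform(*self.contrast_scale)),
            seed=seed,
        )


@dataclass
class PairedDataset:
    """Aligned (degraded input, target) pairs with per-pair provenance."""

    pairs: list[tuple[ImageGrid, ImageGrid]]
    target_mode: str = "GT"  # GT or EGT
    provenance: list[DegradationSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.target_mode not in ("GT", "EGT"):
            raise ValueError(f"target_mode must be GT or EGT, got {self.target_mode!r}")
        for inp, tgt in self.pairs:
            if inp.pixels.shape != tgt.pixels.shape:
                raise ValueError("every pair must be shape-matched")

    def __len__(self) -> int:
        return len(self.pairs)

    def inputs(self) -> list[ImageGrid]:
        return [p[0] for p in self.pairs]

    def targets(self) -> list[ImageGrid]:
        return [p[1] for p in self.pairs]


@dataclass
class ZStack:
    """Simulated focal series of one scene."""

    layers: list[ImageGrid]
    interval_um: float
    focal_index: int

    @property
    def span_um(self) -> float:
        return (len(self.layers) - 1) * self.interval_um


def _soft_ellipse(yy, xx, cy, cx, ry, rx, theta, softness=1.5):
    """Smooth-edged ellipse membership in [0, 1]."""
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    d = np.sqrt((u / rx) ** 2 + (v / ry) ** 2)
    return np.clip((1.0 - d) / (softness / min(rx, ry)) + 0.5, 0.0, 1.0)


def synth_sharp_image(spec: SceneSpec) -> ImageGrid:
    """Render one sharp synthetic field of view.

    Background sits at mid-grey (~0.40) with an oriented illumination ramp;
    cells are mildly brighter soft-edged ellipses (brightfield contrast is
    low) carrying smoothed texture;
    dead cells are small dark disks.  Cell placement retries a bounded number
    of times to limit overlap; the realised count is recorded in ``meta``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)

    theta_bg = rng.uniform(0, 2 * np.pi)
    ramp = ((xx * np.cos(theta_bg) + yy * np.sin(theta_bg)) / max(n - 1, 1))
    ramp = ramp - ramp.mean()
    # brightfield is low-contrast: background mid-grey, cells only mildly brighter
    img = 0.40 + spec.illumination_gradient * ramp

    centers: list[tuple[float, float]] = []
    placed = 0
    lo, hi = spec.cell_radius_range
    for _ in range(spec.n_cells):
        ok = False
        for _attempt in range(20):
            if centers and rng.uniform() < spec.cluster_probability:
                base = centers[rng.integers(len(centers))]
                cy = base[0] + rng.normal(0, 2.0 * hi)
                cx = base[1] + rng.normal(0, 2.0 * hi)
            else:
                cy, cx = rng.uniform(0, n, size=2)
            if not (0 <= cy < n and 0 <= cx < n):
                continue
            if all((cy - oy) ** 2 + (cx - ox) ** 2 > (0.8 * lo) ** 2 for oy, ox in centers):
                ok = True
                break
        if not ok:
            continue
        ry, rx = rng.uniform(lo, hi, size=2)
        theta = rng.uniform(0, np.pi)
        body = _soft_ellipse(yy, xx, cy, cx, ry, rx, theta)
        brightness = rng.uniform(0.12, 0.25)
        img = img + brightness * body
        centers.append((cy, cx))
        placed += 1

    if spec.texture_amplitude > 0:
        noise = rng.standard_normal((n, n))
        texture = ndimage.gaussian_filter(noise, 1.2)
        texture /= max(texture.std(), 1e-12)
        cell_mask = img > 0.46
        img = img + spec.texture_amplitude * 0.3 * texture * cell_mask

    n_dots = rng.poisson(spec.dead_cell_dot_rate)
    for _ in range(n_dots):
        cy, cx = rng.uniform(0, n, size=2)
        r = rng.uniform(2.0, 5.0)
        dot = _soft_ellipse(yy, xx, cy, cx, r, r, 0.0, softness=1.0)
        img = img * (1.0 - 0.85 * dot)

    grid = ImageGrid(np.clip(img, 0.0, 1.0))
    grid.meta.update({"n_cells_requested": spec.n_cells, "n_cells_placed": placed,
                      "seed": spec.seed})
    return grid


def degrade(sharp: ImageGrid, spec: DegradationSpec) -> ImageGrid:
    """Blur -> contrast/brightness scaling about the mean -> additive noise.

    The order mimics optics-then-sensor physics: defocus first, then the
    grey-level attenuation of a poorly lit acquisition, then camera noise.
    An all-identity spec returns the input bit-exactly.
    """
    px = sharp.pixels
    if spec.blur_sigma > 0:
        px = ndimage.gaussian_filter(px, spec.blur_sigma, mode="reflect")
    if spec.contrast_scale != 1.0 or spec.brightness_scale != 1.0:
        m = px.mean()
        px = (px - m) * spec.contrast_scale + m
        px = px * spec.brightness_scale
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        px = px + rng.normal(0.0, spec.noise_sigma, size=px.shape)
    if px is not sharp.pixels:
        px = np.clip(px, 0.0, 1.0)
    out = ImageGrid(px.copy(), pixel_size=sharp.pixel_size,
                    bit_depth_origin=sharp.bit_depth_origin)
    out.meta["degradation"] = spec
    return out


def simulate_z_stack(spec: SceneSpec, n_layers: int, interval_um: float,
                     pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
                     blur_slope: float = BLUR_SIGMA_PER_UM_DEFOCUS) -> ZStack:
    """Simulate a focal series: blur grows linearly with defocus distance.

    The focal (sharpest) layer is the middle index; for an even layer count
    it is the lower middle.  ``sigma_px = blur_slope * |dz_um| / pixel_size``.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if interval_um <= 0:
        raise ValueError("interval_um must be > 0")
    sharp = synth_sharp_image(spec)
    sharp.pixel_size = pixel_size
    focal = (n_layers - 1) // 2
    layers = []
    for i in range(n_layers):
        dz = abs(i - focal) * interval_um
        sigma = blur_slope * dz / pixel_size
        layer = degrade(sharp, DegradationSpec(blur_sigma=sigma, noise_sigma=0.0,
                                               z_offset_layers=i - focal, seed=spec.seed))
        layer.pixel_size = pixel_size
        layer.meta.update({"z_index": i, "dz_um": (i - focal) * interval_um,
                           "blur_sigma_px": sigma})
        layers.append(layer)
    return ZStack(layers=layers, interval_um=interval_um, focal_index=focal)


def build_dataset(n_pairs: int, scene: SceneSpec = SceneSpec(),
                  degradations: DegradationRanges = DegradationRanges(),
                  target_mode: str = "GT", master_seed: int = 0,
                  enhance_params=None) -> PairedDataset:
    """Generate a reproducible paired training/evaluation set.

    Per-pair scene and degradation seeds derive deterministically from
    ``master_seed``.  With ``target_mode="EGT"`` each target is the classic
    unsharp+CLAHE enhancement of the sharp scene (the enhanced-ground-truth
    convention); the parameters used are recorded on the target's ``meta``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if target_mode == "EGT":
        from .classic_enhance import EnhanceParams, traditional_enhance
        params = enhance_params or EnhanceParams()
    master = np.random.default_rng(master_seed)
    pair_seeds = master.integers(0, 2 ** 31 - 1, size=(n_pairs, 2))
    pairs = []
    provenance = []
    for i in range(n_pairs):
        scene_seed, deg_seed = int(pair_seeds[i, 0]), int(pair_seeds[i, 1])
        sharp = synth_sharp_image(replace(scene, seed=scene_seed))
        deg = degradations.sample(np.random.default_rng(deg_seed), seed=deg_seed)
        blurred = degrade(sharp, deg)
        if target_mode == "EGT":
            target = traditional_enhance(sharp, params)
            target.meta["enhance_params"] = params
        else:
            target = sharp
        pairs.append((blurred, target))
        provenance.append(deg)
    return PairedDataset(pairs=pairs, target_mode=target_mode, provenance=provenance)
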