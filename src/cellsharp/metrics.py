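"""Image-quality evaluation suite.

Full-reference: NRMSE, PSNR and multi-scale SSIM between a generated image
and its ground truth.  No-reference: Shannon entropy of the 8-bit grey-level
histogram, mutual information from the joint histogram, and spatial
resolution by Fourier decorrelation analysis.

Conventions: intensities live in [0, 1]; entropy and mutual information are
computed in bits on the 8-bit requantised scale (grey levels 0-255), since
that is the scale on which microscopy archives are stored; PSNR uses peak 1
(equivalently 255 on the 8-bit scale) and the identity case is reported as a
100 dB cap so that reports stay finite.

Decorrelation analysis estimates the highest normalised frequency ``kc``
(Nyquist = 1) at which the image spectrum still carries correlated signal;
the physical resolution is ``2 * pixel_size / kc`` — smaller is better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .image_io import ImageGrid

__all__ = [
    "HistogramSpec", "MetricsReport", "full_reference", "psnr", "nrmse",
    "ms_ssim", "entropy", "mutual_information", "estimate_resolution",
    "metrics_report",
]

PSNR_CAP_DB = 100.0
MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)  # Wang et al. 5-scale


@dataclass(frozen=True)
class HistogramSpec:
    n_bins: int = 256
    # counting happens on the 8-bit requantised scale by default

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class MetricsReport:
    nrmse: float
    psnr_db: float
    ms_ssim: float
    mutual_information_bits: float
    entropy_bits: float
    resolution_um: float
    kc: float


def _px(img) -> np.ndarray:
    return np.asarray(getattr(img, "pixels", img), dtype=np.float64)


# ------------------------------------------------------------ full reference

def nrmse(generated, reference) -> float:
    """RMSE normalised by the reference dynamic range (max - min)."""
    g, r = _px(generated), _px(reference)
    if g.shape != r.shape:
        raise ValueError(f"shape mismatch {g.shape} vs {r.shape}")
    rng = r.max() - r.min()
    if rng == 0:
        raise ValueError("NRMSE undefined for a constant reference image")
    return float(np.sqrt(np.mean((g - r) ** 2)) / rng)


def psnr(generated, reference) -> float:
    """10 log10(1 / MSE) on the [0, 1] scale, capped at 100 dB."""
    g, r = _px(generated), _px(reference)
    if g.shape != r.shape:
        raise ValueError(f"shape mismatch {g.shape} vs {r.shape}")
    mse = float(np.mean((g - r) ** 2))
    if mse == 0:
        return PSNR_CAP_DB
    return float(min(10.0 * np.log10(1.0 / mse), PSNR_CAP_DB))


def _ssim_maps(a: np.ndarray, b: np.ndarray, sigma: float = 1.5,
               k1: float = 0.01, k2: float = 0.03):
    """Gaussian-weighted luminance and contrast-structure maps (peak 1)."""
    c1, c2 = k1 ** 2, k2 ** 2
    f = lambda z: ndimage.gaussian_filter(z, sigma, truncate=3.5, mode="reflect")
    mu_a, mu_b = f(a), f(b)
    var_a = f(a * a) - mu_a ** 2
    var_b = f(b * b) - mu_b ** 2
    cov = f(a * b) - mu_a * mu_b
    lum = (2 * mu_a * mu_b + c1) / (mu_a ** 2 + mu_b ** 2 + c1)
    cs = (2 * cov + c2) / (var_a + var_b + c2)
    return lum, cs


def _downsample2(a: np.ndarray) -> np.ndarray:
    h, w = a.shape[0] // 2 * 2, a.shape[1] // 2 * 2
    a = a[:h, :w]
    return 0.25 * (a[0::2, 0::2] + a[1::2, 0::2] + a[0::2, 1::2] + a[1::2, 1::2])


def ms_ssim(generated, reference, n_scales: int = 5) -> float:
    """Multi-scale SSIM with the standard 5-scale exponents.

    Coarse scales contribute contrast-structure only; the finest retained
    scale contributes the full SSIM.  If the image is too small for the
    requested pyramid, the scale count is reduced (with a warning) and the
    exponents renormalised to sum to one.
    """
    g, r = _px(generated), _px(reference)
    if g.shape != r.shape:
        raise ValueError(f"shape mismatch {g.shape} vs {r.shape}")
    min_side = min(g.shape)
    feasible = 1
    while feasible < n_scales and (min_side // 2 ** feasible) >= 16:
        feasible += 1
    if feasible < n_scales:
        warnings.warn(f"image {g.shape} too small for {n_scales} MS-SSIM scales; "
                      f"using {feasible}", stacklevel=2)
    m = feasible
    weights = np.asarray(MS_SSIM_WEIGHTS[:m], dtype=np.float64)
    weights = weights / weights.sum()
    value = 1.0
    for level in range(m):
        lum, cs = _ssim_maps(g, r)
        if level == m - 1:
            score = float(np.mean(lum * cs))
        else:
            score = float(np.mean(cs))
        value *= max(score, 0.0) ** weights[level]
        if level != m - 1:
            g, r = _downsample2(g), _downsample2(r)
    return float(value)


def full_reference(generated, reference) -> tuple[float, float, float]:
    """(NRMSE, PSNR dB, MS-SSIM) of a generated image against its reference."""
    return (nrmse(generated, reference), psnr(generated, reference),
            ms_ssim(generated, reference))


# ------------------------------------------------------------- no reference

def _quantize(img, n_bins: int) -> np.ndarray:
    px = np.clip(_px(img), 0.0, 1.0)
    return np.minimum((px * n_bins).astype(np.int64), n_bins - 1) if n_bins != 256 \
        else np.round(px * 255.0).astype(np.int64)


def entropy(img, hist: HistogramSpec = HistogramSpec()) -> float:
    """Shannon entropy (bits) of the grey-level histogram after requantisation."""
    q = _quantize(img, hist.n_bins)
    counts = np.bincount(q.ravel(), minlength=hist.n_bins)
    p = counts[counts > 0] / q.size
    return float(-np.sum(p * np.log2(p)) + 0.0)


def mutual_information(a, b, hist: HistogramSpec = HistogramSpec()) -> float:
    """Mutual information (bits) from the joint grey-level histogram."""
    qa, qb = _quantize(a, hist.n_bins), _quantize(b, hist.n_bins)
    if qa.shape != qb.shape:
        raise ValueError(f"shape mismatch {qa.shape} vs {qb.shape}")
    joint = np.zeros((hist.n_bins, hist.n_bins))
    np.add.at(joint, (qa.ravel(), qb.ravel()), 1.0)
    pxy = joint / joint.sum()
    px_ = pxy.sum(axis=1, keepdims=True)
    py_ = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float(np.sum(pxy[mask] * np.log2(pxy[mask] / (px_ @ py_)[mask])))


# ----------------------------------------------------- decorrelation analysis

def _decorrelation_curve(F: np.ndarray, rho: np.ndarray,
                         radii: np.ndarray) -> np.ndarray:
    """d(r) = sum_{|k|<r} |F| / sqrt(sum |F|^2 * #{|k|<r}) via sorted cumsums."""
    absF = np.abs(F).ravel()
    order = np.argsort(rho.ravel())
    rho_sorted = rho.ravel()[order]
    abs_sorted = absF[order]
    cum_abs = np.cumsum(abs_sorted)
    total_sq = np.sum(abs_sorted ** 2)
    if total_sq == 0:
        return np.zeros_like(radii)
    idx = np.searchsorted(rho_sorted, radii, side="right")
    counts = np.maximum(idx, 1)
    num = cum_abs[np.maximum(idx - 1, 0)]
    return num / np.sqrt(total_sq * counts)


def estimate_resolution(img, n_radii: int = 50, n_highpass: int = 10,
                        pixel_size: float | None = None,
                        peak_prominence: float = 1e-3):
    """Decorrelation-analysis resolution estimate.

    The mean-subtracted, edge-apodised image is Fourier transformed; the
    decorrelation function d(r) — the masked cross-correlation between the
    spectrum and its phase-normalised version — is evaluated on ``n_radii``
    mask radii, for the raw spectrum and ``n_highpass`` Gaussian high-pass
    strengths.  ``kc`` is the highest local-maximum frequency over all
    curves; if no curve has a local maximum, the global-maximum radius of
    the unfiltered curve is used and flagged.

    Returns ``(kc, resolution_um)``; access flag/curves via
    ``estimate_resolution.last_details`` set on each call.
    """
    grid = img if isinstance(img, ImageGrid) else ImageGrid(np.asarray(img, dtype=np.float64))
    if min(grid.pixels.shape) < 64:
        raise ValueError("decorrelation analysis needs min side >= 64")
    p = pixel_size if pixel_size is not None else grid.pixel_size
    px = grid.pixels.astype(np.float64)
    px = px - px.mean()

    h, w = px.shape
    wy = signal.windows.tukey(h, alpha=0.25)
    wx = signal.windows.tukey(w, alpha=0.25)
    px = px * np.outer(wy, wx)

    F = np.fft.fftshift(np.fft.fft2(px))
    ky = np.fft.fftshift(np.fft.fftfreq(h)) * 2.0  # Nyquist -> 1
    kx = np.fft.fftshift(np.fft.fftfreq(w)) * 2.0
    rho = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
    inside = rho <= 1.0
    Fv = F[inside]
    rhov = rho[inside]

    radii = np.linspace(1.0 / n_radii, 1.0, n_radii)
    sigmas = np.geomspace(0.05, 1.0, n_highpass)
    curves = [_decorrelation_curve(Fv, rhov, radii)]
    for s in sigmas:
        hp = 1.0 - np.exp(-(rhov ** 2) / (2.0 * s ** 2))
        curves.append(_decorrelation_curve(Fv * hp, rhov, radii))

    peak_freqs = []
    for d in curves:
        peaks, _ = signal.find_peaks(d, prominence=peak_prominence)
        if peaks.size:
            peak_freqs.append(radii[peaks].max())
    flagged = not peak_freqs
    if flagged:
        kc = float(radii[int(np.argmax(curves[0]))])
    else:
        kc = float(max(peak_freqs))
    kc = max(kc, radii[0])
    resolution_um = 2.0 * p / kc
    estimate_resolution.last_details = {"flagged": flagged, "radii": radii,
                                        "curves": curves, "apodization": "tukey-0.25"}
    return kc, float(resolution_um)


def metrics_report(generated, reference) -> MetricsReport:
    """Full panel of the evaluation suite for one (generated, reference) pair."""
    n, p, m = full_reference(generated, reference)
    kc, res = estimate_resolution(generated)
    return MetricsReport(nrmse=n, psnr_db=p, ms_ssim=m,
                         mutual_information_bits=mutual_information(generated, reference),
                         entropy_bits=entropy(generated), resolution_um=res, kc=kc)
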