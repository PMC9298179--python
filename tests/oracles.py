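"""Independent brute-force reference implementations.

Everything here is written as plain scalar loops (or direct textbook
formulas) with no code shared with the package, so that the vectorised
implementations can be checked against them on small fixtures.
"""

from __future__ import annotations

import math

import numpy as np


def rec_loss_loops(x: np.ndarray, xh: np.ndarray) -> float:
    b, c, h, w = x.shape
    total = 0.0
    for bi in range(b):
        for ci in range(c):
            for i in range(h):
                for j in range(w):
                    total += (x[bi, ci, i, j] - xh[bi, ci, i, j]) ** 2
    return total / (b * c * h * w)


def tv_loss_loops(xh: np.ndarray) -> float:
    b, c, h, w = xh.shape
    total = 0.0
    for bi in range(b):
        for ci in range(c):
            for i in range(h):
                for j in range(w):
                    if i + 1 < h:
                        total += (xh[bi, ci, i + 1, j] - xh[bi, ci, i, j]) ** 2
                    if j + 1 < w:
                        total += (xh[bi, ci, i, j + 1] - xh[bi, ci, i, j]) ** 2
    return total / (b * c * h * w)


def gram_loops(f: np.ndarray) -> np.ndarray:
    c, h, w = f.shape
    g = np.zeros((c, c))
    for a in range(c):
        for b in range(c):
            s = 0.0
            for i in range(h):
                for j in range(w):
                    s += f[a, i, j] * f[b, i, j]
            g[a, b] = s
    return g


def feature_loss_loops(taps_x: list[np.ndarray], taps_xh: list[np.ndarray]) -> float:
    total = 0.0
    for fx, fxh in zip(taps_x, taps_xh):
        b, c, h, w = fx.shape
        s = 0.0
        for bi in range(b):
            for ci in range(c):
                for i in range(h):
                    for j in range(w):
                        s += (fx[bi, ci, i, j] - fxh[bi, ci, i, j]) ** 2
        total += s / (b * c * h * w)
    return total


def style_loss_loops(taps_x: list[np.ndarray], taps_xh: list[np.ndarray]) -> float:
    total = 0.0
    for fx, fxh in zip(taps_x, taps_xh):
        b, c, h, w = fx.shape
        s = 0.0
        for bi in range(b):
            dg = gram_loops(fx[bi]) - gram_loops(fxh[bi])
            for a in range(c):
                for bb in range(c):
                    s += dg[a, bb] ** 2
        total += s / (b * c * h * w)
    return total


def adversarial_losses_loops(d_real, d_fake, eps=1e-7):
    dr = [min(max(v, eps), 1 - eps) for v in d_real]
    df = [min(max(v, eps), 1 - eps) for v in d_fake]
    l_d = -sum(math.log(r) + math.log(1 - f) for r, f in zip(dr, df)) / len(dr)
    l_g = -sum(math.log(f) for f in df) / len(df)
    return l_d, l_g


def unsharp_loops(img: np.ndarray, radius: float, amount: float) -> np.ndarray:
    """Direct truncated-Gaussian convolution with reflect boundary."""
    h, w = img.shape
    half = int(4.0 * radius + 0.5)
    kernel = np.array([math.exp(-(t ** 2) / (2 * radius ** 2))
                       for t in range(-half, half + 1)])
    kernel /= kernel.sum()

    def reflect(i, n):
        while i < 0 or i >= n:
            if i < 0:
                i = -i - 1
            if i >= n:
                i = 2 * n - i - 1
        return i

    blur_rows = np.zeros_like(img)
    for i in range(h):
        for j in range(w):
            s = 0.0
            for t in range(-half, half + 1):
                s += kernel[t + half] * img[reflect(i + t, h), j]
            blur_rows[i, j] = s
    blurred = np.zeros_like(img)
    for i in range(h):
        for j in range(w):
            s = 0.0
            for t in range(-half, half + 1):
                s += kernel[t + half] * blur_rows[i, reflect(j + t, w)]
            blurred[i, j] = s
    return np.clip(img + amount * (img - blurred), 0.0, 1.0)


def mutual_information_table(a_levels: np.ndarray, b_levels: np.ndarray,
                             n_bins: int = 256) -> float:
    """MI in bits by explicit joint-table enumeration over quantised levels."""
    n = a_levels.size
    joint: dict[tuple[int, int], float] = {}
    pa: dict[int, float] = {}
    pb: dict[int, float] = {}
    for x, y in zip(a_levels.ravel(), b_levels.ravel()):
        joint[(x, y)] = joint.get((x, y), 0.0) + 1.0 / n
        pa[x] = pa.get(x, 0.0) + 1.0 / n
        pb[y] = pb.get(y, 0.0) + 1.0 / n
    mi = 0.0
    for (x, y), p in joint.items():
        mi += p * math.log2(p / (pa[x] * pb[y]))
    return mi


def ssim_single_scale_loops(a: np.ndarray, b: np.ndarray, sigma=1.5,
                            k1=0.01, k2=0.03):
    """(mean luminance*cs, mean cs) with an explicit Gaussian window."""
    from scipy import ndimage  # filtering only; the reduction is explicit

    c1, c2 = k1 ** 2, k2 ** 2
    f = lambda z: ndimage.gaussian_filter(z, sigma, truncate=3.5, mode="reflect")
    mu_a, mu_b = f(a), f(b)
    va = f(a * a) - mu_a ** 2
    vb = f(b * b) - mu_b ** 2
    cov = f(a * b) - mu_a * mu_b
    h, w = a.shape
    ssim_sum = 0.0
    cs_sum = 0.0
    for i in range(h):
        for j in range(w):
            lum = (2 * mu_a[i, j] * mu_b[i, j] + c1) / (mu_a[i, j] ** 2 + mu_b[i, j] ** 2 + c1)
            cs = (2 * cov[i, j] + c2) / (va[i, j] + vb[i, j] + c2)
            ssim_sum += lum * cs
            cs_sum += cs
    return ssim_sum / (h * w), cs_sum / (h * w)


def ms_ssim_reference(a: np.ndarray, b: np.ndarray, weights) -> float:
    """Single-pass multi-scale reduction using the loop SSIM at each scale."""
    m = len(weights)
    weights = [w / sum(weights) for w in weights]
    value = 1.0
    for level in range(m):
        ssim_v, cs_v = ssim_single_scale_loops(a, b)
        value *= max(ssim_v if level == m - 1 else cs_v, 0.0) ** weights[level]
        if level != m - 1:
            h, w = a.shape[0] // 2 * 2, a.shape[1] // 2 * 2
            a = 0.25 * (a[0:h:2, 0:w:2] + a[1:h:2, 0:w:2] + a[0:h:2, 1:w:2] + a[1:h:2, 1:w:2])
            b = 0.25 * (b[0:h:2, 0:w:2] + b[1:h:2, 0:w:2] + b[0:h:2, 1:w:2] + b[1:h:2, 1:w:2])
    return value
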