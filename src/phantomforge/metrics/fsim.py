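"""Feature similarity index (FSIM) for grayscale images.

FSIM scores local similarity by combining phase congruency (PC) — a
contrast-invariant measure of feature significance computed from log-Gabor
filter banks — with gradient magnitude (GM), and pools the local similarity
weighted by the maximum phase congruency of the two images:

    S_PC = (2 PC1 PC2 + T1) / (PC1² + PC2² + T1)
    S_G  = (2 G1 G2 + T2) / (G1² + G2² + T2)
    FSIM = Σ S_PC · S_G · PCm / Σ PCm,   PCm = max(PC1, PC2)

Constants follow the standard parameterization (T1 = 0.85, T2 = 160 on a
0–255 intensity scale; 4 scales, 4 orientations, minimum wavelength 6,
scale multiplier 2, σ_f/f = 0.55). Inputs are rescaled to 0–255 using a
shared data range before scoring so CT (HU) and MRI (a.u.) images are
handled uniformly.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve, uniform_filter

__all__ = ["fsim", "phase_congruency", "gradient_magnitude"]

_T1 = 0.85
_T2 = 160.0


def _lowpassfilter(shape: tuple[int, int], cutoff: float = 0.45, n: int = 15) -> np.ndarray:
    rows, cols = shape
    fy = (np.arange(rows) - rows // 2) / rows
    fx = (np.arange(cols) - cols // 2) / cols
    radius = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    return np.fft.ifftshift(1.0 / (1.0 + (radius / cutoff) ** (2 * n)))


def _filter_bank(shape, nscale, norient, min_wavelength, mult, sigma_on_f,
                 d_theta_sigma=1.2):
    rows, cols = shape
    fy = (np.arange(rows) - rows // 2) / rows
    fx = (np.arange(cols) - cols // 2) / cols
    radius = np.fft.ifftshift(np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2))
    radius[0, 0] = 1.0
    theta = np.fft.ifftshift(np.arctan2(-fy[:, None], fx[None, :]))
    lp = _lowpassfilter(shape)

    log_gabors = []
    for s in range(nscale):
        wavelength = min_wavelength * mult**s
        f0 = 1.0 / wavelength
        lg = np.exp(-(np.log(radius / f0) ** 2) / (2 * np.log(sigma_on_f) ** 2))
        lg *= lp
        lg[0, 0] = 0.0
        log_gabors.append(lg)

    spreads = []
    theta_sigma = np.pi / norient / d_theta_sigma
    for o in range(norient):
        angle = o * np.pi / norient
        ds = np.sin(theta) * np.cos(angle) - np.cos(theta) * np.sin(angle)
        dc = np.cos(theta) * np.cos(angle) + np.sin(theta) * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spreads.append(np.exp(-(dtheta**2) / (2 * theta_sigma**2)))
    return log_gabors, spreads


def phase_congruency(img: np.ndarray, nscale: int = 4, norient: int = 4,
                     min_wavelength: float = 6.0, mult: float = 2.0,
                     sigma_on_f: float = 0.55, k: float = 2.0,
                     eps: float = 1e-4) -> np.ndarray:
    """Phase congruency map (orientation-summed, noise-compensated)."""
    img = np.asarray(img, dtype=np.float64)
    imfft = np.fft.fft2(img)
    log_gabors, spreads = _filter_bank(img.shape, nscale, norient,
                                       min_wavelength, mult, sigma_on_f)
    energy_all = np.zeros(img.shape)
    an_all = np.zeros(img.shape)
    for spread in spreads:
        sum_e = np.zeros(img.shape)
        sum_o = np.zeros(img.shape)
        sum_an = np.zeros(img.shape)
        tau = 0.0
        for s, lg in enumerate(log_gabors):
            eo = np.fft.ifft2(imfft * lg * spread)
            an = np.abs(eo)
            sum_an += an
            sum_e += eo.real
            sum_o += eo.imag
            if s == 0:
                tau = np.median(an) / np.sqrt(np.log(4))
        x_energy = np.sqrt(sum_e**2 + sum_o**2) + eps
        mean_e, mean_o = sum_e / x_energy, sum_o / x_energy
        energy = np.zeros(img.shape)
        for lg in log_gabors:
            eo = np.fft.ifft2(imfft * lg * spread)
            e, o = eo.real, eo.imag
            energy += e * mean_e + o * mean_o - np.abs(e * mean_o - o * mean_e)
        # Rayleigh-statistics noise threshold from the smallest-scale response
        total_tau = tau * (1 - (1 / mult) ** nscale) / (1 - 1 / mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2)
        noise_sigma = total_tau * np.sqrt((4 - np.pi) / 2)
        threshold = noise_mean + k * noise_sigma
        energy = np.maximum(energy - threshold, 0.0)
        energy_all += energy
        an_all += sum_an
    return energy_all / (an_all + eps)


_SCHARR_X = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]], dtype=np.float64) / 16.0


def gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gx = convolve(np.asarray(img, dtype=np.float64), _SCHARR_X, mode="nearest")
    gy = convolve(np.asarray(img, dtype=np.float64), _SCHARR_X.T, mode="nearest")
    return np.sqrt(gx**2 + gy**2)


def fsim(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> float:
    """FSIM between two grayscale images of equal shape; 1 for identical."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo if hi > lo else 1.0
        a, b = a - lo, b - lo
    scale = 255.0 / data_range
    a, b = a * scale, b * scale

    # Standard pre-smoothing and decimation for large images.
    f = max(1, round(min(a.shape) / 256))
    if f > 1:
        a = uniform_filter(a, size=f)[::f, ::f]
        b = uniform_filter(b, size=f)[::f, ::f]

    pc1 = phase_congruency(a)
    pc2 = phase_congruency(b)
    g1 = gradient_magnitude(a)
    g2 = gradient_magnitude(b)
    s_pc = (2 * pc1 * pc2 + _T1) / (pc1**2 + pc2**2 + _T1)
    s_g = (2 * g1 * g2 + _T2) / (g1**2 + g2**2 + _T2)
    pcm = np.maximum(pc1, pc2)
    denom = pcm.sum()
    if denom == 0:
        return 1.0  # both images featureless
    return float((s_pc * s_g * pcm).sum() / denom)
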