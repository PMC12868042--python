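"""Unpaired realism statistics comparing generated and patient cohorts:
liver noise magnitude, radial noise power spectrum (NPS) with Pearson
comparison, and cohort-average histogram correlation (HistCC).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.ndimage as ndi

from ..volumes import Volume

__all__ = [
    "NoiseReport", "noise_magnitude", "radial_nps", "nps_correlation",
    "hist_correlation", "ct_histogram_edges", "largest_box_in_mask",
]

#: Default ROI for NPS estimation (rows, cols, slices understood as 64×64×20).
DEFAULT_NPS_ROI = (20, 64, 64)


def noise_magnitude(vol, organ_mask) -> float:
    """Population standard deviation of voxel intensities inside the mask.

    Applied to a large, mostly homogeneous organ (typically the liver) this
    measures the noise magnitude of the image.
    """
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    mask = np.asarray(organ_mask, dtype=bool)
    if mask.shape != data.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {data.shape}")
    if not mask.any():
        raise ValueError("empty organ mask")
    return float(np.std(data[mask]))


def radial_nps(roi: np.ndarray, spacing_mm=(1.0, 1.0, 1.0), n_bins: int | None = None):
    """Radially averaged noise power spectrum of a 3D ROI.

    Per axial slice: subtract the slice mean, 2D FFT, squared modulus scaled
    by Δx·Δy/(Nx·Ny); spectra are averaged over slices, then binned into
    equal-width annuli of radial spatial frequency (1/mm).

    Returns ``(freq_centers, power)``.
    """
    roi = np.asarray(roi, dtype=np.float64)
    if roi.ndim != 3:
        raise ValueError("ROI must be 3D (slices, rows, cols)")
    ns, nr, nc = roi.shape
    if nr < 16 or nc < 16:
        raise ValueError(f"ROI in-plane size must be >= 16, got {(nr, nc)}")
    dr, dc = float(spacing_mm[1]), float(spacing_mm[2])
    spec = np.zeros((nr, nc))
    for k in range(ns):
        sl = roi[k] - roi[k].mean()
        f = np.fft.fft2(sl)
        spec += (np.abs(f) ** 2) * (dr * dc) / (nr * nc)
    spec /= ns

    fr = np.fft.fftfreq(nr, d=dr)
    fc = np.fft.fftfreq(nc, d=dc)
    radius = np.sqrt(fr[:, None] ** 2 + fc[None, :] ** 2)
    f_nyq = min(0.5 / dr, 0.5 / dc)
    if n_bins is None:
        n_bins = min(nr, nc) // 4
    edges = np.linspace(0.0, f_nyq, n_bins + 1)
    idx = np.digitize(radius.ravel(), edges) - 1
    # the zero-frequency component carries no noise information (detrended)
    keep = (idx >= 0) & (idx < n_bins) & (radius.ravel() > 0)
    power = np.bincount(idx[keep], weights=spec.ravel()[keep], minlength=n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nonempty = counts > 0
    return centers[nonempty], power[nonempty] / counts[nonempty]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("curves must share binning")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("correlation undefined for a constant curve")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def nps_correlation(curve1, curve2) -> float:
    """Pearson correlation of two radial NPS curves (same binning)."""
    c1 = curve1[1] if isinstance(curve1, tuple) else curve1
    c2 = curve2[1] if isinstance(curve2, tuple) else curve2
    return _pearson(c1, c2)


def ct_histogram_edges(step: float = 10.0) -> np.ndarray:
    """Fixed CT histogram edges spanning the clip range in `step` HU bins."""
    return np.arange(-1000.0, 1047.0 + step, step)


def _volume_hist(vol, edges, body_only: bool, background: float) -> np.ndarray:
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    vals = data.ravel()
    if body_only:
        vals = vals[vals > background]
        if vals.size == 0:
            vals = data.ravel()
    hist, _ = np.histogram(vals, bins=edges, density=True)
    return hist


def hist_correlation(cohort_a, cohort_b, edges=None, body_only: bool = True,
                     background: float = -1000.0) -> float:
    """Pearson correlation between the cohort-mean intensity histograms.

    Each volume contributes a density histogram on shared bin edges; the two
    cohort-mean histograms are then correlated. With ``body_only`` (default)
    background-valued voxels are excluded, so the statistic reflects tissue
    intensities rather than the air outside the body.
    """
    if not cohort_a or not cohort_b:
        raise ValueError("cohorts must be non-empty")
    if edges is None:
        edges = ct_histogram_edges()
    ha = np.mean([_volume_hist(v, edges, body_only, background) for v in cohort_a], axis=0)
    hb = np.mean([_volume_hist(v, edges, body_only, background) for v in cohort_b], axis=0)
    return _pearson(ha, hb)


def largest_box_in_mask(mask: np.ndarray, box_shape=DEFAULT_NPS_ROI):
    """Origin (slice, row, col) of a box of ``box_shape`` fully inside the mask,
    chosen where the mask erosion is deepest; None when the mask cannot hold it."""
    mask = np.asarray(mask, dtype=bool)
    inside = ndi.minimum_filter(mask.astype(np.uint8), size=box_shape,
                                mode="constant", cval=0)
    if not inside.any():
        return None
    dist = ndi.distance_transform_edt(mask)
    dist[inside == 0] = -1
    center = np.unravel_index(int(np.argmax(dist)), mask.shape)
    return tuple(int(c - s // 2) for c, s in zip(center, box_shape))


@dataclasses.dataclass
class NoiseReport:
    """Cohort-level unpaired metrics."""

    nm_per_volume_a: list
    nm_per_volume_b: list
    nm_mean_a: float
    nm_mean_b: float
    nps_ncc: float | None
    hist_cc: float
    roi_shape: tuple
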