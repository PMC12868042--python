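"""Paired (slice-aligned) similarity metrics between generated and reference
volumes: MAE, SSIM, FSIM, Canny edge preservation/generation ratios,
center-patch LPIPS (pluggable backend), and the synthetic-CT validation set
(PSNR, NCC, RMSE, per-channel MAE for air/bone/soft tissue).

Volume-level values are the mean of per-slice values, matching the common
"compute per slice pair, then average" reporting convention.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from skimage.feature import canny
from skimage.metrics import structural_similarity

from .fsim import fsim as _fsim_impl
from ..volumes import CT_RANGE, LabelVolume, Modality, Volume

__all__ = [
    "CannyParams", "EdgeMaps", "PairedReport", "UndefinedMetricError",
    "mae", "ssim", "fsim", "edge_maps", "egr", "epr", "lpips_center",
    "psnr", "ncc", "rmse", "channel_mae", "threshold_channels",
    "evaluate_paired_volumes",
]


class UndefinedMetricError(ValueError):
    """A metric is mathematically undefined on this input (e.g. no edges)."""


def _pair(a, b):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return a, b


def mae(a, b, mask=None) -> float:
    """Mean absolute intensity difference, optionally restricted to a mask."""
    a, b = _pair(a, b)
    diff = np.abs(a - b)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise UndefinedMetricError("empty mask")
        diff = diff[mask]
    return float(diff.mean())


def rmse(a, b) -> float:
    a, b = _pair(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(a, b, data_range: float) -> float:
    """20 log10(range) - 10 log10(MSE), in dB; +inf for identical inputs."""
    a, b = _pair(a, b)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return math.inf
    return 20.0 * math.log10(data_range) - 10.0 * math.log10(mse)


def ncc(a, b) -> float:
    """Pearson correlation of the flattened voxel vectors (affine-invariant)."""
    a, b = _pair(a, b)
    a, b = a.ravel(), b.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise UndefinedMetricError("NCC undefined for zero-variance input")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def ssim(a, b, data_range: float) -> float:
    """Standard SSIM with Gaussian window (σ = 1.5, K1 = 0.01, K2 = 0.03)."""
    a, b = _pair(a, b)
    return float(
        structural_similarity(
            a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=0.01, K2=0.03,
        )
    )


def fsim(a, b, data_range: float | None = None) -> float:
    return _fsim_impl(a, b, data_range=data_range)


@dataclasses.dataclass
class CannyParams:
    """Canny detector settings recorded with every report.

    Hysteresis thresholds are fractions of each image's dynamic range.
    """

    sigma: float = 1.0
    low_fraction: float = 0.10
    high_fraction: float = 0.20


@dataclasses.dataclass
class EdgeMaps:
    original: np.ndarray
    generated: np.ndarray
    params: CannyParams


def _canny(img: np.ndarray, p: CannyParams) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    rng = img.max() - img.min()
    if rng == 0:
        return np.zeros(img.shape, dtype=bool)
    return canny(img, sigma=p.sigma, low_threshold=p.low_fraction * rng,
                 high_threshold=p.high_fraction * rng)


def edge_maps(original, generated, params: CannyParams | None = None) -> EdgeMaps:
    """Binary Canny edge maps of both images with identical parameters."""
    a, b = _pair(original, generated)
    p = params or CannyParams()
    return EdgeMaps(_canny(a, p), _canny(b, p), p)


def egr(maps: EdgeMaps) -> float:
    """Edge generation ratio: |edges(generated)| / |edges(original)|."""
    n_orig = int(maps.original.sum())
    if n_orig == 0:
        raise UndefinedMetricError("original edge map is empty")
    return float(maps.generated.sum() / n_orig)


def epr(maps: EdgeMaps) -> float:
    """Edge preservation ratio: |edges(original) ∩ edges(generated)| / |edges(original)|."""
    n_orig = int(maps.original.sum())
    if n_orig == 0:
        raise UndefinedMetricError("original edge map is empty")
    return float((maps.original & maps.generated).sum() / n_orig)


def _center_patch(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape
    if h < size or w < size:
        ph, pw = max(size - h, 0), max(size - w, 0)
        img = np.pad(img, ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)))
        h, w = img.shape
    r0, c0 = (h - size) // 2, (w - size) // 2
    return img[r0 : r0 + size, c0 : c0 + size]


def lpips_center(a_slice, b_slice, backend=None, size: int = 256):
    """Perceptual distance on the centred size×size patch pair.

    ``backend`` is a callable ``(patch_a, patch_b) -> float`` wrapping a
    learned feature extractor. Without a backend the metric is reported as
    unavailable (``None``), never as an exception.
    """
    if backend is None:
        return None
    a, b = _pair(a_slice, b_slice)
    return float(backend(_center_patch(a, size), _center_patch(b, size)))


DEFAULT_CHANNEL_THRESHOLDS = (-200.0, 200.0)


def threshold_channels(ref_ct: np.ndarray,
                       thresholds=DEFAULT_CHANNEL_THRESHOLDS) -> np.ndarray:
    """Three-channel label map from CT thresholding: 1 air, 2 soft, 3 bone."""
    lo, hi = thresholds
    ref_ct = np.asarray(ref_ct)
    out = np.full(ref_ct.shape, 2, dtype=np.int32)
    out[ref_ct < lo] = 1
    out[ref_ct > hi] = 3
    return out


def channel_mae(sct, ref_ct, labels3=None,
                thresholds=DEFAULT_CHANNEL_THRESHOLDS) -> dict:
    """MAE restricted to the air / soft / bone channels of the reference CT.

    Channels come from ``labels3`` (1 = air, 2 = soft, 3 = bone) or by
    thresholding the reference. Empty channels are reported as None.
    """
    a = sct.data if isinstance(sct, Volume) else np.asarray(sct)
    r = ref_ct.data if isinstance(ref_ct, Volume) else np.asarray(ref_ct)
    if labels3 is None:
        lab = threshold_channels(r, thresholds)
    else:
        lab = labels3.labels if isinstance(labels3, LabelVolume) else np.asarray(labels3)
    out = {}
    for name, code in (("air", 1), ("soft", 2), ("bone", 3)):
        m = lab == code
        out[name] = mae(a, r, mask=m) if m.any() else None
    return out


@dataclasses.dataclass
class PairedReport:
    """Per-slice arrays and volume-level summaries of the paired metrics."""

    per_slice: dict
    summary: dict
    canny: CannyParams
    n_slices: int
    n_excluded_edge_slices: int


def evaluate_paired_volumes(generated: Volume, reference: Volume,
                            data_range: float | None = None,
                            canny_params: CannyParams | None = None,
                            lpips_backend=None) -> PairedReport:
    """Slice-wise paired evaluation of two co-registered volumes.

    ``data_range`` defaults to the CT clip span (2047) for CT volumes and the
    reference volume's own range otherwise. Slices whose reference edge map is
    empty are excluded from the EPR/EGR averages (the count is reported).
    """
    if generated.shape != reference.shape:
        raise ValueError(f"shape mismatch {generated.shape} vs {reference.shape}")
    if data_range is None:
        if reference.modality == Modality.CT:
            data_range = CT_RANGE[1] - CT_RANGE[0]
        else:
            data_range = float(reference.data.max() - reference.data.min()) or 1.0
    p = canny_params or CannyParams()
    per: dict[str, list] = {k: [] for k in
                            ("mae", "ssim", "fsim", "epr", "egr", "lpips")}
    excluded = 0
    for k in range(reference.shape[0]):
        ref_sl, gen_sl = reference.data[k], generated.data[k]
        per["mae"].append(mae(gen_sl, ref_sl))
        per["ssim"].append(ssim(gen_sl, ref_sl, data_range))
        per["fsim"].append(fsim(gen_sl, ref_sl, data_range))
        maps = edge_maps(ref_sl, gen_sl, p)
        if maps.original.sum() == 0:
            excluded += 1
            per["epr"].append(None)
            per["egr"].append(None)
        else:
            per["epr"].append(epr(maps))
            per["egr"].append(egr(maps))
        per["lpips"].append(lpips_center(gen_sl, ref_sl, backend=lpips_backend))
    summary = {}
    for key, vals in per.items():
        kept = [v for v in vals if v is not None]
        if kept:
            summary[key] = {"mean": float(np.mean(kept)), "sd": float(np.std(kept))}
    return PairedReport(per, summary, p, reference.shape[0], excluded)
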