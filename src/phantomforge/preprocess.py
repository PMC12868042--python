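"""CT/MRI preparation: clipping, body masking, background suppression and
[-1, +1] normalization with exact inversion.

The CT chain mirrors routine synthesis-model preprocessing: clip to
[-1000, +1047] HU, build a per-slice body mask (threshold at -110 HU, fill
holes, Sobel edge refinement, largest connected component), force the
background to -1000 HU, then rescale linearly to [-1, +1]. MRI volumes are
normalized with their own per-volume range and a background of 0.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.ndimage as ndi
from skimage import filters, morphology

from .volumes import CT_RANGE, Modality, Volume

__all__ = [
    "clip_ct",
    "body_mask",
    "apply_background",
    "normalize",
    "denormalize",
    "BODY_THRESHOLD_HU",
]

log = logging.getLogger(__name__)

#: HU threshold separating body tissue from air/couch background.
BODY_THRESHOLD_HU = -110.0


class ModalityError(ValueError):
    pass


def clip_ct(vol: Volume) -> Volume:
    """Clip a CT volume to the fixed [-1000, +1047] HU window (idempotent)."""
    if vol.modality != Modality.CT:
        raise ModalityError(f"clip_ct expects a CT volume, got {vol.modality}")
    lo, hi = CT_RANGE
    return vol.with_data(np.clip(vol.data, lo, hi), intensity_range=(lo, hi))


def _mask_slice(sl: np.ndarray, threshold: float) -> np.ndarray:
    fg = sl >= threshold
    if not fg.any():
        return fg
    fg = ndi.binary_fill_holes(fg)
    # Edge refinement: a 1-px dilated Sobel boundary band temporarily seals
    # single-pixel leaks so hole filling captures the interior; band pixels
    # outside the original foreground are then discarded again.
    edge = filters.sobel(fg.astype(np.float32)) > 0
    band = morphology.dilation(edge, morphology.disk(1))
    filled = ndi.binary_fill_holes(fg | band)
    fg = fg | (filled & ~band)
    fg = ndi.binary_fill_holes(fg)
    lab, n = ndi.label(fg)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    return fg


def body_mask(vol: Volume, threshold: float = BODY_THRESHOLD_HU) -> np.ndarray:
    """Per-slice body mask of a clipped CT volume.

    Pipeline per axial slice: threshold >= -110 HU, binary hole filling,
    Sobel-based boundary refinement, keep the largest connected component.
    Slices without any foreground yield an empty mask slice (logged).
    """
    mask = np.zeros(vol.shape, dtype=bool)
    empty = 0
    for k in range(vol.shape[0]):
        m = _mask_slice(vol.data[k], threshold)
        if not m.any():
            empty += 1
        mask[k] = m
    if empty:
        log.info("body_mask: %d slice(s) had empty foreground", empty)
    return mask


def apply_background(vol: Volume, mask: np.ndarray) -> Volume:
    """Set voxels outside the mask to air (-1000 HU for CT, 0 for MRI)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    fill = -1000.0 if vol.modality == Modality.CT else 0.0
    out = vol.data.copy()
    out[~mask] = fill
    return vol.with_data(out)


def normalize(vol: Volume) -> Volume:
    """Linear map of ``intensity_range`` onto [-1, +1].

    CT volumes use the fixed clip range; MRI (and any volume without a stored
    range) use the per-volume (min, max), which is recorded for inversion.
    """
    rng = vol.intensity_range
    if rng is None:
        if vol.modality == Modality.CT:
            rng = CT_RANGE
        else:
            rng = (float(vol.data.min()), float(vol.data.max()))
    lo, hi = rng
    if hi == lo:
        raise ValueError("degenerate intensity range: hi == lo")
    out = 2.0 * (vol.data - lo) / (hi - lo) - 1.0
    return vol.with_data(out.astype(np.float32), intensity_range=(lo, hi))


def denormalize(vol_or_data, intensity_range: tuple[float, float] | None = None):
    """Exact inverse of :func:`normalize` onto the given physical range.

    Accepts a Volume (range taken from metadata unless overridden) or a bare
    array with an explicit range. Inputs are clamped to [-1, +1] first so tiny
    generator overshoots do not leave the physical range.
    """
    if isinstance(vol_or_data, Volume):
        rng = intensity_range or vol_or_data.intensity_range
        if rng is None:
            raise ValueError("denormalize needs an intensity range")
        data = denormalize(vol_or_data.data, rng)
        return vol_or_data.with_data(data, intensity_range=rng)
    if intensity_range is None:
        raise ValueError("denormalize needs an intensity range")
    lo, hi = intensity_range
    x = np.clip(np.asarray(vol_or_data, dtype=np.float32), -1.0, 1.0)
    return ((x + 1.0) * 0.5 * (hi - lo) + lo).astype(np.float32)
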