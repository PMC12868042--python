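"""2D patch extraction, deterministic inference tiling and mean fusion.

Training uses random patches on a stride lattice; inference tiles every axial
slice deterministically and reassembles the network outputs by averaging
overlapping patches ("mean patch fusion"). With 348×348 slices, 220×220
patches and stride 64 the lattice is {0, 64, 128}² — nine patches that cover
the slice exactly, since 128 + 220 = 348.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.transform import resize

__all__ = [
    "Patch",
    "PatchGrid",
    "tile_origins",
    "extract_training_patches",
    "resize_patch",
    "tile_for_inference",
    "fuse_mean",
]


@dataclasses.dataclass
class Patch:
    slice_idx: int
    row0: int
    col0: int
    size: int
    data: np.ndarray  # (size, size)


@dataclasses.dataclass
class PatchGrid:
    patches: list[Patch]
    source_shape: tuple[int, int]  # in-plane (rows, cols) of the source slice(s)

    def __len__(self) -> int:
        return len(self.patches)


def tile_origins(dim: int, patch_size: int, stride: int) -> list[int]:
    """Stride-lattice origins 0, s, 2s, ... plus a clamped final origin at
    ``dim - patch_size`` when the lattice misses the far edge."""
    if patch_size > dim:
        raise ValueError(f"patch size {patch_size} exceeds dimension {dim}")
    last = dim - patch_size
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)
    return origins


def extract_training_patches(
    vol,
    patch_size: int,
    stride: int,
    per_slice: int = 4,
    seed: int = 0,
    foreground_mask: np.ndarray | None = None,
    min_foreground: float = 0.2,
) -> PatchGrid:
    """Random per-slice training patches on the stride lattice.

    ``per_slice`` patches are drawn uniformly without replacement from the
    candidate origins of each slice (all candidates when fewer exist);
    deterministic for a given seed. When ``foreground_mask`` is given,
    candidates with less than ``min_foreground`` fraction of foreground are
    dropped first (falling back to all candidates if none survive) — this
    avoids patches that are mostly background.
    """
    data = np.asarray(vol) if isinstance(vol, (np.ndarray, list)) else vol.data
    if data.ndim == 2:
        data = data[None]
    if per_slice < 1:
        raise ValueError("per_slice must be >= 1")
    nr, nc = data.shape[1:]
    rows = tile_origins(nr, patch_size, stride)
    cols = tile_origins(nc, patch_size, stride)
    candidates = [(r, c) for r in rows for c in cols]
    rng = np.random.default_rng(seed)
    patches: list[Patch] = []
    for k in range(data.shape[0]):
        cands = candidates
        if foreground_mask is not None:
            kept = [
                (r, c)
                for r, c in candidates
                if foreground_mask[k, r : r + patch_size, c : c + patch_size].mean()
                >= min_foreground
            ]
            if kept:
                cands = kept
        take = min(per_slice, len(cands))
        idx = rng.choice(len(cands), size=take, replace=False)
        for i in sorted(int(j) for j in idx):
            r, c = cands[i]
            patches.append(Patch(k, r, c, patch_size,
                                 data[k, r : r + patch_size, c : c + patch_size].copy()))
    return PatchGrid(patches, (nr, nc))


def resize_patch(patch: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of a square patch to size×size (values stay in range)."""
    patch = np.asarray(patch, dtype=np.float32)
    if patch.shape[0] != patch.shape[1]:
        raise ValueError(f"patch must be square, got {patch.shape}")
    if patch.shape[0] == size:
        return patch.copy()
    out = resize(patch, (size, size), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def tile_for_inference(slice2d: np.ndarray, patch_size: int, stride: int) -> PatchGrid:
    """Deterministic full tiling of one slice with guaranteed coverage."""
    slice2d = np.asarray(slice2d)
    if slice2d.ndim != 2:
        raise ValueError("tile_for_inference expects a 2D slice")
    if stride > patch_size:
        raise ValueError("stride must not exceed patch_size (coverage would have gaps)")
    nr, nc = slice2d.shape
    patches = [
        Patch(0, r, c, patch_size, slice2d[r : r + patch_size, c : c + patch_size].copy())
        for r in tile_origins(nr, patch_size, stride)
        for c in tile_origins(nc, patch_size, stride)
    ]
    return PatchGrid(patches, (nr, nc))


def fuse_mean(grid: PatchGrid, predicted: list[np.ndarray]) -> np.ndarray:
    """Average overlapping patch predictions back onto the source slice.

    Each prediction must already be back at its patch's native size and in
    physical units. Every pixel of the output must be covered by at least one
    patch (always true for grids from :func:`tile_for_inference`).
    """
    if len(predicted) != len(grid.patches):
        raise ValueError(f"{len(predicted)} predictions for {len(grid.patches)} patches")
    acc = np.zeros(grid.source_shape, dtype=np.float64)
    cnt = np.zeros(grid.source_shape, dtype=np.int64)
    for patch, pred in zip(grid.patches, predicted):
        pred = np.asarray(pred)
        if pred.shape != (patch.size, patch.size):
            raise ValueError(
                f"prediction shape {pred.shape} != native patch size {(patch.size,) * 2}"
            )
        sl = np.s_[patch.row0 : patch.row0 + patch.size, patch.col0 : patch.col0 + patch.size]
        acc[sl] += pred
        cnt[sl] += 1
    if (cnt == 0).any():
        raise ValueError("fusion left uncovered pixels")
    return (acc / cnt).astype(np.float32)
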