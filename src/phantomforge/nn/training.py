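"""Unpaired two-domain training loop and patch-based volume inference.

The bundle holds two generators (G: X→Y, phantom→patient; F: Y→X) and two
PatchGAN discriminators. At every iteration each of the four networks is
updated independently: each generator minimizes its full composite objective
(adversarial + both cycle terms + intensity + gradient-difference) w.r.t. its
own weights with the other networks frozen, and each discriminator minimizes
the halved real/fake BCE using a fake drawn from its history buffer.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .adam import Adam
from .buffer import ImageBuffer
from .layers import Sequential
from .losses import (
    LossBreakdown,
    loss_adversarial,
    loss_cycle,
    loss_discriminator,
    loss_gdl,
    loss_generator_total,
    loss_intensity,
)
from .networks import build_discriminator, build_generator

__all__ = ["GanConfig", "GanBundle", "train", "predict_volume",
           "save_checkpoint", "load_checkpoint"]


@dataclasses.dataclass
class GanConfig:
    """Hyper-parameters of one translation network pair.

    The fixed weights follow standard unpaired-translation practice:
    cycle-consistency weight 10, adversarial weight 1, generator learning
    rate 2e-4. λ_int / λ_gdl and the discriminator learning rate are the
    tunable knobs. Paper-scale defaults: 9 residual blocks, 64 base filters,
    256×256 inputs, 150 epochs, buffer of 50.
    """

    lambda_cyc: float = 10.0
    lambda_adv: float = 1.0
    lambda_int: float = 1.0
    lambda_gdl: float = 1.0
    lr_g: float = 2e-4
    lr_d: float = 2e-5
    epochs: int = 150
    batch_size: int = 1
    buffer_K: int = 50
    n_res_blocks: int = 9
    base_filters: int = 64
    input_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        for lam in ("lambda_cyc", "lambda_adv", "lambda_int", "lambda_gdl"):
            if getattr(self, lam) < 0:
                raise ValueError(f"{lam} must be >= 0")
        if self.lr_g <= 0 or self.lr_d <= 0:
            raise ValueError("learning rates must be > 0")
        if self.buffer_K < 1 or self.n_res_blocks < 1:
            raise ValueError("buffer_K and n_res_blocks must be >= 1")


@dataclasses.dataclass
class GanBundle:
    G: Sequential  # phantom -> patient
    F: Sequential  # patient -> phantom
    D_X: Sequential
    D_Y: Sequential
    cfg: GanConfig
    opt_G: Adam | None = None
    opt_F: Adam | None = None
    opt_DX: Adam | None = None
    opt_DY: Adam | None = None
    buffer_X: ImageBuffer | None = None
    buffer_Y: ImageBuffer | None = None

    def zero_grad(self) -> None:
        for net in (self.G, self.F, self.D_X, self.D_Y):
            net.zero_grad()


def init_bundle(cfg: GanConfig) -> GanBundle:
    ss = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    bundle = GanBundle(
        G=build_generator(cfg, rngs[0]),
        F=build_generator(cfg, rngs[1]),
        D_X=build_discriminator(cfg, rngs[2]),
        D_Y=build_discriminator(cfg, rngs[3]),
        cfg=cfg,
        buffer_X=ImageBuffer(cfg.buffer_K, rngs[4]),
        buffer_Y=ImageBuffer(cfg.buffer_K, rngs[4]),
    )
    bundle.opt_G = Adam(bundle.G.params(), cfg.lr_g)
    bundle.opt_F = Adam(bundle.F.params(), cfg.lr_g)
    bundle.opt_DX = Adam(bundle.D_X.params(), cfg.lr_d)
    bundle.opt_DY = Adam(bundle.D_Y.params(), cfg.lr_d)
    bundle._train_rng = rngs[5]  # type: ignore[attr-defined]
    return bundle


def _as_chw(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    return img[None] if img.ndim == 2 else img


def _check_finite(value: float, component: str) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite loss in component {component!r}")


def _generator_step(gen, other, disc, opt, x, y, cfg, bundle) -> LossBreakdown:
    """Update ``gen`` on its full composite objective; other nets frozen."""
    bundle.zero_grad()
    parts = LossBreakdown()

    # Terms flowing through gen's translation of x: adversarial, intensity,
    # gdl, and the forward cycle (through the frozen other generator).
    fake = gen.forward(x)
    d_out = disc.forward(fake)
    parts.adv, g_adv = loss_adversarial(d_out, with_grad=True)
    grad_fake = cfg.lambda_adv * disc.backward(g_adv)
    parts.intensity, g_int = loss_intensity(x, fake, with_grad=True)
    grad_fake += cfg.lambda_int * g_int
    parts.gdl, g_gdl = loss_gdl(x, fake, with_grad=True)
    grad_fake += cfg.lambda_gdl * g_gdl
    rec = other.forward(fake)
    parts.cyc_fwd, g_cyc = loss_cycle(x, rec, with_grad=True)
    grad_fake += cfg.lambda_cyc * other.backward(g_cyc)
    gen.backward(grad_fake)

    # Backward cycle: gen closes the loop on the opposite domain sample.
    fake_back = other.forward(y)
    rec_back = gen.forward(fake_back)
    parts.cyc_bwd, g_cyc_b = loss_cycle(y, rec_back, with_grad=True)
    gen.backward(cfg.lambda_cyc * g_cyc_b)

    parts.total = loss_generator_total(parts, cfg)
    for name in ("adv", "cyc_fwd", "cyc_bwd", "intensity", "gdl", "total"):
        _check_finite(getattr(parts, name), name)
    opt.step()
    return parts


def _discriminator_step(disc, opt, real, fake, bundle) -> float:
    from .losses import EPS

    bundle.zero_grad()
    d_real = disc.forward(real)
    disc.backward(-0.5 / (np.clip(d_real, EPS, 1.0) * d_real.size))
    d_fake = disc.forward(fake)
    disc.backward(0.5 / ((1.0 - np.clip(d_fake, 0.0, 1.0 - EPS)) * d_fake.size))
    val = loss_discriminator(d_real, d_fake)
    _check_finite(val, "disc")
    opt.step()
    return val


def train(domain_X_patches, domain_Y_patches, cfg: GanConfig,
          callback=None) -> tuple[GanBundle, list[dict]]:
    """Train on two unpaired patch collections normalized to [-1, 1].

    Returns the bundle and a per-epoch history of mean loss components
    (keys ``G_*`` for the X→Y direction, ``F_*`` mirrored, ``D_X``/``D_Y``).
    Fully deterministic for a given config seed. ``callback(epoch, bundle,
    epoch_record)`` runs after every epoch (e.g. for checkpoints).
    """
    xs = [_as_chw(p) for p in domain_X_patches]
    ys = [_as_chw(p) for p in domain_Y_patches]
    if not xs or not ys:
        raise ValueError("both domains must be non-empty")
    bundle = init_bundle(cfg)
    rng = bundle._train_rng
    history: list[dict] = []
    n_iter = max(len(xs), len(ys))
    for epoch in range(cfg.epochs):
        order_x = rng.permutation(len(xs))
        order_y = rng.permutation(len(ys))
        sums: dict[str, float] = {}
        for it in range(n_iter):
            x = xs[order_x[it % len(xs)]]
            y = ys[order_y[it % len(ys)]]
            g_parts = _generator_step(bundle.G, bundle.F, bundle.D_Y,
                                      bundle.opt_G, x, y, cfg, bundle)
            f_parts = _generator_step(bundle.F, bundle.G, bundle.D_X,
                                      bundle.opt_F, y, x, cfg, bundle)
            fake_y = bundle.G.forward(x)
            fake_x = bundle.F.forward(y)
            d_y = _discriminator_step(bundle.D_Y, bundle.opt_DY, y,
                                      bundle.buffer_Y.push_sample(fake_y), bundle)
            d_x = _discriminator_step(bundle.D_X, bundle.opt_DX, x,
                                      bundle.buffer_X.push_sample(fake_x), bundle)
            rec = {
                **{f"G_{k}": getattr(g_parts, k) for k in
                   ("adv", "cyc_fwd", "cyc_bwd", "intensity", "gdl", "total")},
                **{f"F_{k}": getattr(f_parts, k) for k in
                   ("adv", "cyc_fwd", "cyc_bwd", "intensity", "gdl", "total")},
                "D_Y": d_y, "D_X": d_x,
            }
            for k, v in rec.items():
                sums[k] = sums.get(k, 0.0) + v
        epoch_record = {k: v / n_iter for k, v in sums.items()}
        epoch_record["epoch"] = epoch
        history.append(epoch_record)
        if callback is not None:
            callback(epoch, bundle, epoch_record)
    return bundle, history


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict_volume(generator, vol, patch_size: int, stride: int,
                   input_size: int = 256):
    """Translate a whole volume slice-by-slice with patch tiling + mean fusion.

    Per axial slice: normalize to [-1, 1] with the volume's intensity range,
    tile into patches, bilinear-resize each to the network input size, run the
    generator, resize back to native patch size, map back to physical units,
    and average overlapping patches. ``generator`` is any object with a
    ``forward`` method (or callable) mapping (1, s, s) → (1, s, s).
    """
    from ..patching import fuse_mean, resize_patch, tile_for_inference
    from ..preprocess import denormalize, normalize
    from ..volumes import Volume

    if not isinstance(vol, Volume):
        raise TypeError("predict_volume expects a Volume")
    norm = normalize(vol)
    rng_phys = norm.intensity_range
    fwd = generator.forward if hasattr(generator, "forward") else generator
    out = np.empty_like(norm.data)
    for k in range(norm.shape[0]):
        grid = tile_for_inference(norm.data[k], patch_size, stride)
        preds = []
        for patch in grid.patches:
            inp = resize_patch(patch.data, input_size)[None].astype(np.float64)
            pred = np.asarray(fwd(inp))[0]
            pred = resize_patch(pred.astype(np.float32), patch.size)
            preds.append(denormalize(pred, rng_phys))
        out[k] = fuse_mean(grid, preds)
    return vol.with_data(out, intensity_range=rng_phys)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(bundle: GanBundle, path: str | Path) -> None:
    """Single-file weight container (NPZ) with the config embedded."""
    arrays = {}
    for name, net in (("G", bundle.G), ("F", bundle.F),
                      ("DX", bundle.D_X), ("DY", bundle.D_Y)):
        for i, p in enumerate(net.params()):
            arrays[f"{name}_{i}"] = p.value
    arrays["config_json"] = np.frombuffer(
        json.dumps(dataclasses.asdict(bundle.cfg)).encode(), dtype=np.uint8
    )
    np.savez(Path(path), **arrays)


def load_checkpoint(path: str | Path) -> GanBundle:
    with np.load(Path(path)) as data:
        cfg = GanConfig(**json.loads(bytes(data["config_json"].tobytes()).decode()))
        bundle = init_bundle(cfg)
        for name, net in (("G", bundle.G), ("F", bundle.F),
                          ("DX", bundle.D_X), ("DY", bundle.D_Y)):
            for i, p in enumerate(net.params()):
                p.value[...] = data[f"{name}_{i}"]
    return bundle
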