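"""Composite CycleGAN losses: BCE adversarial terms, L1 cycle/intensity terms
and the first-order gradient-difference loss, with their analytic gradients.

The generator objective for the phantom→patient direction is

    L(G) = λ_adv · L_GAN + λ_cyc · (L_cyc_fwd + L_cyc_bwd)
         + λ_int · L_int + λ_gdl · L_gdl

where L_GAN = mean(-log D(G(x))), the cycle and intensity terms are mean
absolute differences, and L_gdl penalizes squared differences between the
absolute horizontal/vertical first-order gradients of input and translation.
The discriminator loss is the halved sum of its real and fake BCE terms:
L(D) = ½ [BCE(1, D(real)) + BCE(0, D(fake))], giving ln 2 at the
uninformative fixed point D ≡ ½.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "EPS",
    "LossBreakdown",
    "loss_adversarial",
    "loss_cycle",
    "loss_intensity",
    "loss_gdl",
    "loss_generator_total",
    "loss_discriminator",
]

#: Clamp inside every log term.
EPS = 1e-7


def loss_adversarial(d_out: np.ndarray, with_grad: bool = False):
    """mean(-log d) over the discriminator map; 0 when the map is all ones."""
    d = np.maximum(np.asarray(d_out, dtype=np.float64), EPS)
    val = float(np.mean(-np.log(d)))
    if not with_grad:
        return val
    return val, -1.0 / (d * d.size)


def _l1(a: np.ndarray, b: np.ndarray, with_grad: bool):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    diff = a - b
    val = float(np.mean(np.abs(diff)))
    if not with_grad:
        return val
    return val, np.sign(diff) / diff.size


def loss_cycle(x: np.ndarray, x_cycled: np.ndarray, with_grad: bool = False):
    """Mean absolute difference between an image and its cycled reconstruction.

    With ``with_grad`` the gradient is w.r.t. ``x_cycled``.
    """
    if not with_grad:
        return _l1(x_cycled, x, False)
    return _l1(x_cycled, x, True)


def loss_intensity(x: np.ndarray, g_x: np.ndarray, with_grad: bool = False):
    """Mean absolute difference between input and its translation (anchors
    organ intensities). Gradient w.r.t. ``g_x``."""
    if not with_grad:
        return _l1(g_x, x, False)
    return _l1(g_x, x, True)


def loss_gdl(x: np.ndarray, y: np.ndarray, with_grad: bool = False):
    """Gradient-difference loss between input ``x`` and translation ``y``.

    Sum over valid positions of (| |∇v x| − |∇v y| |)² + (| |∇h x| − |∇h y| |)²
    with one-pixel backward differences, divided by the total number of
    gradient terms. Adding a constant to either image leaves it unchanged.
    Gradient (if requested) is w.r.t. ``y``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    # operate on the trailing two axes; leading channel axis optional
    gvx = np.abs(np.diff(x, axis=-2))
    gvy_raw = np.diff(y, axis=-2)
    ghx = np.abs(np.diff(x, axis=-1))
    ghy_raw = np.diff(y, axis=-1)
    dv = np.abs(gvy_raw) - gvx
    dh = np.abs(ghy_raw) - ghx
    n = dv.size + dh.size
    val = float((np.sum(dv**2) + np.sum(dh**2)) / n)
    if not with_grad:
        return val
    gv = 2.0 * dv * np.sign(gvy_raw) / n  # d/d(∇v y)
    gh = 2.0 * dh * np.sign(ghy_raw) / n
    grad = np.zeros_like(y)
    # ∇v y[i] = y[i+1] - y[i] under np.diff along axis -2
    sl_hi = (Ellipsis, slice(1, None), slice(None))
    sl_lo = (Ellipsis, slice(None, -1), slice(None))
    grad[sl_hi] += gv
    grad[sl_lo] -= gv
    grad[..., :, 1:] += gh
    grad[..., :, :-1] -= gh
    return val, grad


@dataclasses.dataclass
class LossBreakdown:
    """Per-direction generator loss components plus the discriminator loss."""

    adv: float = 0.0
    cyc_fwd: float = 0.0
    cyc_bwd: float = 0.0
    intensity: float = 0.0
    gdl: float = 0.0
    total: float = 0.0
    disc: float = 0.0


def loss_generator_total(parts: LossBreakdown, cfg) -> float:
    """Weighted recombination of the generator loss components."""
    return (
        cfg.lambda_adv * parts.adv
        + cfg.lambda_cyc * (parts.cyc_fwd + parts.cyc_bwd)
        + cfg.lambda_int * parts.intensity
        + cfg.lambda_gdl * parts.gdl
    )


def loss_discriminator(d_real: np.ndarray, d_fake: np.ndarray,
                       with_grad: bool = False):
    """½ [mean(-log d_real) + mean(-log(1 - d_fake))]."""
    dr = np.clip(np.asarray(d_real, dtype=np.float64), EPS, 1.0)
    df = np.clip(np.asarray(d_fake, dtype=np.float64), 0.0, 1.0 - EPS)
    val = float(0.5 * (np.mean(-np.log(dr)) + np.mean(-np.log1p(-df))))
    if not with_grad:
        return val
    g_real = -0.5 / (dr * dr.size)
    g_fake = 0.5 / ((1.0 - df) * df.size)
    return val, g_real, g_fake
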