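"""Generator and discriminator architectures.

Generator: ResNet encoder-decoder — a 7×7 stem plus two stride-2 encoding
convolutions, ``n_res_blocks`` residual blocks at the bottleneck, and two
decoding stages of bilinear upsampling followed by 3×3 convolution (avoiding
checkerboard artifacts), all with reflection padding and instance
normalization, finishing in a tanh head so outputs live in (-1, 1).

Discriminator: 70×70 PatchGAN — five 4×4 convolutions with strides
(2, 2, 2, 1, 1) and padding 1, instance norm on the middle layers, sigmoid
map output. A 256×256 input yields a 30×30 map whose each unit has a 70×70
receptive field.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    Conv2d,
    InstanceNorm,
    LeakyReLU,
    ReLU,
    ReflectionPad,
    Residual,
    Sequential,
    Sigmoid,
    Tanh,
    UpsampleBilinear2x,
)

__all__ = ["build_generator", "build_discriminator", "receptive_field",
           "DISCRIMINATOR_LAYOUT"]

#: (kernel, stride, padding) of the five PatchGAN convolutions.
DISCRIMINATOR_LAYOUT = ((4, 2, 1), (4, 2, 1), (4, 2, 1), (4, 1, 1), (4, 1, 1))


class ConfigError(ValueError):
    pass


def build_generator(cfg, rng: np.random.Generator | None = None) -> Sequential:
    """ResNet generator per the config (see :class:`~..training.GanConfig`)."""
    if cfg.input_size % 4 != 0:
        raise ConfigError(f"input_size must be divisible by 4, got {cfg.input_size}")
    rng = rng or np.random.default_rng(cfg.seed)
    f = cfg.base_filters
    layers: list = [
        ReflectionPad(3), Conv2d(1, f, 7, rng=rng), InstanceNorm(), ReLU(),
        ReflectionPad(1), Conv2d(f, 2 * f, 3, stride=2, rng=rng), InstanceNorm(), ReLU(),
        ReflectionPad(1), Conv2d(2 * f, 4 * f, 3, stride=2, rng=rng), InstanceNorm(), ReLU(),
    ]
    for _ in range(cfg.n_res_blocks):
        body = Sequential(
            ReflectionPad(1), Conv2d(4 * f, 4 * f, 3, rng=rng), InstanceNorm(), ReLU(),
            ReflectionPad(1), Conv2d(4 * f, 4 * f, 3, rng=rng), InstanceNorm(),
        )
        layers.append(Residual(body))
    layers += [
        UpsampleBilinear2x(), ReflectionPad(1), Conv2d(4 * f, 2 * f, 3, rng=rng),
        InstanceNorm(), ReLU(),
        UpsampleBilinear2x(), ReflectionPad(1), Conv2d(2 * f, f, 3, rng=rng),
        InstanceNorm(), ReLU(),
        ReflectionPad(3), Conv2d(f, 1, 7, rng=rng), Tanh(),
    ]
    return Sequential(*layers)


def build_discriminator(cfg, rng: np.random.Generator | None = None) -> Sequential:
    """70×70 PatchGAN discriminator.

    Inputs smaller than the 70-pixel receptive field are allowed (every map
    unit then sees the whole patch), but the five-conv stack needs at least
    24 pixels to produce a non-empty output map.
    """
    if cfg.input_size < 24:
        raise ConfigError(f"discriminator input must be >= 24, got {cfg.input_size}")
    rng = rng or np.random.default_rng(cfg.seed)
    f = cfg.base_filters
    widths = (1, f, 2 * f, 4 * f, 8 * f, 1)
    layers: list = []
    last = len(DISCRIMINATOR_LAYOUT) - 1
    for i, (k, s, p) in enumerate(DISCRIMINATOR_LAYOUT):
        layers.append(Conv2d(widths[i], widths[i + 1], k, stride=s, pad=p, rng=rng))
        if i == last:
            layers.append(Sigmoid())
        else:
            if i > 0:  # no norm on the first layer (canonical PatchGAN)
                layers.append(InstanceNorm())
            layers.append(LeakyReLU(0.2))
    return Sequential(*layers)


def receptive_field(layout=DISCRIMINATOR_LAYOUT) -> int:
    """Receptive-field side of one output unit, by the standard recurrence
    r_in = (r_out - 1) * stride + kernel applied from the last layer back."""
    r = 1
    for k, s, _ in reversed(layout):
        r = (r - 1) * s + k
    return r
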