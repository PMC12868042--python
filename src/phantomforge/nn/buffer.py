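"""History buffer of generated images used when updating the discriminators.

Instead of always showing the discriminator the most recent fake, a pool of
the last K fakes is kept; once full, each new fake either replaces a random
stored one (and the stored one is returned) or is returned directly, each
with probability ½. This stabilizes adversarial training.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ImageBuffer"]


class ImageBuffer:
    def __init__(self, capacity: int, rng: np.random.Generator):
        if capacity < 1:
            raise ValueError("buffer capacity must be >= 1")
        self.capacity = capacity
        self.rng = rng
        self.images: list[np.ndarray] = []

    def __len__(self) -> int:
        return len(self.images)

    def push_sample(self, img: np.ndarray) -> np.ndarray:
        img = np.array(img, copy=True)
        if len(self.images) < self.capacity:
            self.images.append(img)
            return img
        if self.rng.random() < 0.5:
            idx = int(self.rng.integers(self.capacity))
            out = self.images[idx]
            self.images[idx] = img
            return out
        return img
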