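"""Adam optimizer with bias-corrected moment estimates."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Adam over an aligned (params, grads) pair of array lists.

    Defaults follow the common recommendation: learning rate 1e-3, first and
    second moment decay 0.9 and 0.999.
    """

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
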