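"""Optimizers for the NumPy layers."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "SGD"]


class Adam:
    """Adam with default moments and decoupled weight decay.

    Decay multiplies weights by ``(1 - lr * weight_decay)`` each step and is
    skipped for parameters flagged ``decay=False`` (biases).
    """

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            if self.weight_decay and p.decay:
                p.value *= 1.0 - self.lr * self.weight_decay
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class SGD:
    def __init__(self, params, lr=1e-2, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay

    def step(self) -> None:
        for p in self.params:
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            p.value -= self.lr * g

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
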