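"""Optimizers for the numpy layer stack."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Adam:
    """Adam with bias correction; one slot pair per (layer, parameter)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self, root: Layer) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for lyr in root.iter_layers():
            if not getattr(lyr, "trainable", True):
                continue
            for name, p in lyr.params.items():
                g = lyr.grads.get(name)
                if g is None:
                    continue
                key = (id(lyr), name)
                m = self._m.setdefault(key, np.zeros_like(p))
                v = self._v.setdefault(key, np.zeros_like(p))
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class SGD:
    """Plain gradient descent, matching the textbook update rule."""

    def __init__(self, lr: float):
        self.lr = lr

    def step(self, root: Layer) -> None:
        for lyr in root.iter_layers():
            if not getattr(lyr, "trainable", True):
                continue
            for name, p in lyr.params.items():
                g = lyr.grads.get(name)
                if g is not None:
                    p -= self.lr * g
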