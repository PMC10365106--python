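"""Adam optimizer (adaptive-moment gradient descent)."""

from __future__ import annotations

import numpy as np

from . import autograd
from .autograd import Tensor

__all__ = ["Adam"]


class Adam:
    """Adam over a single flat buffer.

    On construction every parameter's ``data`` becomes a view into one
    contiguous float32 vector, so the moment updates and the parameter step
    are three vectorized operations regardless of how many (small) parameter
    arrays the model has.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        total = sum(p.data.size for p in params)
        self.flat = np.empty(total, dtype=autograd.DTYPE)
        self._slices = []
        off = 0
        for p in params:
            size = p.data.size
            sl = slice(off, off + size)
            self.flat[sl] = p.data.ravel()
            p.data = self.flat[sl].reshape(p.data.shape)
            self._slices.append(sl)
            off += size
        self.m = np.zeros(total, dtype=autograd.DTYPE)
        self.v = np.zeros(total, dtype=autograd.DTYPE)
        self._g = np.zeros(total, dtype=autograd.DTYPE)

    def step(self) -> None:
        self.t += 1
        g = self._g
        for p, sl in zip(self.params, self._slices):
            if p.grad is None:
                g[sl] = 0.0
            else:
                g[sl] = p.grad.ravel()
        m, v = self.m, self.v
        m += (1.0 - self.b1) * (g - m)
        v += (1.0 - self.b2) * (g * g - v)
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        self.flat -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
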