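"""Adam optimiser (Kingma & Ba) over Parameter lists."""

from __future__ import annotations

import numpy as np

from .layers import DTYPE, Parameter


class Adam:
    """Standard Adam with bias correction; default moments (0.9, 0.999)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError(f"learning rate must be > 0, got {lr}")
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.value -= (self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)).astype(DTYPE)
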