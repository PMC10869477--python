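"""ADAM optimizer for the NumPy network stack."""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter


class Adam:
    """ADAM with the conventional bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 0.005, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params: list[Parameter] = list(params)
        if not self.params:
            raise ValueError("no parameters to optimize")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = np.asarray(p.grad, dtype=np.float64)
            if not np.all(np.isfinite(g)):
                raise FloatingPointError("non-finite gradient encountered")
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
                      ).astype(p.data.dtype)
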