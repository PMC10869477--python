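"""Layer objects composing the autodiff primitives.

Each layer owns its :class:`Parameter` tensors and is called with a
``training`` flag and, where stochastic, an RNG. Layers report their
trainable parameter count so architecture bookkeeping can be checked
against closed-form expectations.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor


class Layer:
    name = "layer"

    def params(self) -> list[Parameter]:
        return []

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def state_dict(self) -> dict:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.params())}

    def load_state(self, state: dict):
        for i, p in enumerate(self.params()):
            p.data = state[f"p{i}"].copy()


class ConvTemporal(Layer):
    """F kernels of shape (1, K) applied to every channel of a single map."""

    name = "conv_temporal"

    def __init__(self, n_filters: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32, pad_mode: str = "same"):
        scale = 1.0 / np.sqrt(kernel)
        self.w = Parameter(rng.uniform(-scale, scale,
                                       (n_filters, kernel)).astype(dtype))
        self.pad_mode = pad_mode

    def params(self):
        return [self.w]

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ad.conv_time(x, self.w, pad_mode=self.pad_mode)


class DepthwiseSpatial(Layer):
    """Spatial (C, 1) depthwise convolution with channel multiplier F2."""

    name = "depthwise_spatial"

    def __init__(self, f1: int, f2: int, channels: int,
                 rng: np.random.Generator, dtype=np.float32):
        scale = 1.0 / np.sqrt(channels)
        self.w = Parameter(rng.uniform(-scale, scale,
                                       (f1, f2, channels)).astype(dtype))

    def params(self):
        return [self.w]

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ad.depthwise_spatial(x, self.w)


class BatchNorm(Layer):
    name = "batchnorm"

    def __init__(self, n_maps: int, dtype=np.float32, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_maps, dtype=dtype))
        self.beta = Parameter(np.zeros(n_maps, dtype=dtype))
        self.running_mean = np.zeros(n_maps, dtype=np.float64)
        self.running_var = np.ones(n_maps, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def state_dict(self):
        d = super().state_dict()
        d["running_mean"] = self.running_mean.copy()
        d["running_var"] = self.running_var.copy()
        return d

    def load_state(self, state):
        super().load_state(state)
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()

    def __call__(self, x: Tensor, training: bool = False,
                 update_running: bool = True) -> Tensor:
        return ad.batchnorm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, training,
                            momentum=self.momentum, eps=self.eps,
                            update_running=update_running)


class ReLU(Layer):
    name = "relu"

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ad.relu(x)


class AvgPoolTime(Layer):
    name = "avgpool_time"

    def __init__(self, pool: int):
        self.pool = pool

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ad.avgpool_time(x, self.pool)


class Dropout(Layer):
    name = "dropout"

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        if not training or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an RNG")
        keep = (rng.random(x.data.shape) >= self.p).astype(x.data.dtype)
        return ad.mul(x, keep / (1.0 - self.p))


class Dense(Layer):
    name = "dense"

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32, bias: bool = True):
        scale = 1.0 / np.sqrt(d_in)
        self.w = Parameter(rng.uniform(-scale, scale, (d_in, d_out)).astype(dtype))
        self.b = Parameter(np.zeros(d_out, dtype=dtype)) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        y = ad.matmul(x, self.w)
        if self.b is not None:
            y = ad.add(y, self.b)
        return y
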