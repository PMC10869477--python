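"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the seizure-prediction network and its
adversarial heads need: broadcast arithmetic, matrix products, the two
convolution types of the architecture (temporal FFT convolution and a
depthwise spatial contraction), batch normalization, pooling, softmax /
cross-entropy, binary cross-entropy on logits, and a gradient-reversal
node. Gradients are exercised against finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft

__all__ = [
    "Tensor", "Parameter", "add", "sub", "mul", "matmul", "reshape",
    "concat", "relu", "avgpool_time", "softmax", "cross_entropy_logits",
    "bce_logits", "conv_time", "depthwise_spatial", "batchnorm",
    "grad_reverse", "mean_", "sum_",
]


class Tensor:
    """A node in the computation graph.

    ``parents`` is a tuple of ``(tensor, vjp)`` pairs where ``vjp`` maps the
    upstream gradient to this parent's gradient contribution.
    """

    __slots__ = ("data", "grad", "parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data)
        self.parents = tuple(parents)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in self.parents
        )
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node.parents:
                stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node.parents:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, vjp in node.parents:
                if not parent.requires_grad:
                    continue
                contrib = vjp(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + contrib
                else:
                    grads[key] = contrib
        # a leaf may also be the output itself
        if not self.parents and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return Tensor(a.data + b.data, [
        (a, lambda g: _unbroadcast(g, a.data.shape)),
        (b, lambda g: _unbroadcast(g, b.data.shape)),
    ])


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return Tensor(a.data - b.data, [
        (a, lambda g: _unbroadcast(g, a.data.shape)),
        (b, lambda g: _unbroadcast(-g, b.data.shape)),
    ])


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return Tensor(a.data * b.data, [
        (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
        (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
    ])


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return Tensor(a.data @ b.data, [
        (a, lambda g: g @ b.data.T),
        (b, lambda g: a.data.T @ g),
    ])


def reshape(a, shape):
    a = _as_tensor(a)
    old = a.data.shape
    return Tensor(a.data.reshape(shape), [(a, lambda g: g.reshape(old))])


def concat(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]
        return vjp

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  [(t, make_vjp(i)) for i, t in enumerate(tensors)])


def sum_(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    shape = a.data.shape

    def vjp(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g, shape).copy()

    return Tensor(a.data.sum(axis=axis, keepdims=keepdims), [(a, vjp)])


def mean_(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    shape = a.data.shape
    n = a.data.size if axis is None else np.prod(
        [shape[ax] for ax in np.atleast_1d(axis)])

    def vjp(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g, shape).copy() / n

    return Tensor(a.data.mean(axis=axis, keepdims=keepdims), [(a, vjp)])


def relu(a):
    a = _as_tensor(a)
    mask = a.data > 0
    return Tensor(a.data * mask, [(a, lambda g: g * mask)])


def avgpool_time(a, pool: int):
    """Average pooling with window/stride ``pool`` along the last axis."""
    a = _as_tensor(a)
    *lead, T = a.data.shape
    if T % pool:
        raise ValueError(f"time axis of length {T} not divisible by pool {pool}")
    out = a.data.reshape(*lead, T // pool, pool).mean(axis=-1)

    def vjp(g):
        return np.repeat(g, pool, axis=-1).reshape(a.data.shape) / pool

    return Tensor(out, [(a, vjp)])


def softmax(logits):
    logits = _as_tensor(logits)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)

    def vjp(g):
        return p * (g - (g * p).sum(axis=-1, keepdims=True))

    return Tensor(p, [(logits, vjp)])


def cross_entropy_logits(logits, y):
    """Mean cross-entropy of integer labels ``y`` against row logits."""
    logits = _as_tensor(logits)
    y = np.asarray(y)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1))
    loss = float((lse - z[np.arange(n), y]).mean())
    p = np.exp(z) / np.exp(z).sum(axis=-1, keepdims=True)

    def vjp(g):
        dz = p.copy()
        dz[np.arange(n), y] -= 1.0
        return (g * dz / n).astype(logits.data.dtype)

    return Tensor(np.asarray(loss, dtype=logits.data.dtype), [(logits, vjp)])


def bce_logits(z, targets, weights=None):
    """Weighted mean binary cross-entropy on logits ``z`` (1-D)."""
    z = _as_tensor(z)
    t = np.asarray(targets, dtype=z.data.dtype)
    w = np.ones_like(t) if weights is None else np.asarray(
        weights, dtype=z.data.dtype)
    n = z.data.shape[0]
    x = z.data
    # softplus(x) - t*x, numerically stable
    sp = np.logaddexp(0.0, x)
    loss = float((w * (sp - t * x)).mean())
    sig = 1.0 / (1.0 + np.exp(-x))

    def vjp(g):
        return (g * w * (sig - t) / n).astype(z.data.dtype)

    return Tensor(np.asarray(loss, dtype=z.data.dtype), [(z, vjp)])


def grad_reverse(x, lambda_: float):
    """Identity in the forward pass; scales the gradient by ``-lambda_``.

    The gradient-reversal trick turns the adversarial min-max between the
    feature encoder and the domain discriminator into a single minimization.
    """
    if lambda_ < 0:
        raise ValueError("lambda_ must be non-negative")
    x = _as_tensor(x)
    lam = float(lambda_)
    return Tensor(x.data, [(x, lambda g: -lam * g)])


# ---------------------------------------------------------------------------
# convolutions


def conv_time(x, w, pad_mode: str = "same"):
    """Temporal cross-correlation of (B, 1, C, T) input with (F, K) kernels.

    Returns (B, F, C, T) for 'same' padding (left pad (K-1)//2) or
    (B, F, C, T-K+1) for 'valid'. Computed by FFT; each kernel is applied to
    every channel independently, matching a 2D convolution with kernel
    shape (1, K) on a single input map.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    B, one, C, T = x.data.shape
    if one != 1:
        raise ValueError("conv_time expects a single input map axis")
    F, K = w.data.shape
    pl = (K - 1) // 2 if pad_mode == "same" else 0
    pr = K - 1 - pl
    Tout = T if pad_mode == "same" else T - K + 1
    n = sfft.next_fast_len(T + K - 1, real=True)

    Xf = sfft.rfft(x.data, n, axis=-1)                      # (B,1,C,nf)
    Wrf = sfft.rfft(w.data[:, ::-1], n, axis=-1)            # (F,nf)
    z = sfft.irfft(Xf * Wrf[None, :, None, :], n, axis=-1)  # linear conv
    if pad_mode == "same":
        y = z[..., pr:pr + T]
    else:
        y = z[..., K - 1:K - 1 + Tout]
    y = np.ascontiguousarray(y, dtype=x.data.dtype)

    Wf = None  # lazily computed unflipped kernel spectrum for the x-vjp

    def vjp_x(g):
        nonlocal Wf
        if Wf is None:
            Wf = sfft.rfft(w.data, n, axis=-1)
        Gf = sfft.rfft(g, n, axis=-1)                        # (B,F,C,nf)
        dz = sfft.irfft((Gf * Wf[None, :, None, :]).sum(axis=1, keepdims=True),
                        n, axis=-1)
        off = pl if pad_mode == "same" else 0
        return np.ascontiguousarray(dz[..., off:off + T], dtype=x.data.dtype)

    def vjp_w(g):
        Gf = sfft.rfft(g, n, axis=-1)                        # (B,F,C,nf)
        spec = (np.conj(Gf) * Xf).sum(axis=(0, 2))           # (F,nf)
        r = sfft.irfft(spec, n, axis=-1)                     # lag correlation
        off = pl if pad_mode == "same" else 0
        idx = (np.arange(K) - off) % n
        return np.ascontiguousarray(r[:, idx], dtype=w.data.dtype)

    return Tensor(y, [(x, vjp_x), (w, vjp_w)])


def depthwise_spatial(x, w):
    """Depthwise convolution with kernel (C, 1) and multiplier F2.

    ``x`` is (B, F1, C, T), ``w`` is (F1, F2, C); each of the F1 temporal
    maps is collapsed over channels by F2 learned spatial filters, giving
    (B, F1*F2, 1, T). Output map ordering is temporal-filter major.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    B, F1, C, T = x.data.shape
    F1w, F2, Cw = w.data.shape
    if (F1w, Cw) != (F1, C):
        raise ValueError("depthwise kernel shape mismatch")
    y = np.einsum("bfct,fgc->bfgt", x.data, w.data, optimize=True)
    y = np.ascontiguousarray(y.reshape(B, F1 * F2, 1, T), dtype=x.data.dtype)

    def vjp_x(g):
        g4 = g.reshape(B, F1, F2, T)
        return np.einsum("bfgt,fgc->bfct", g4, w.data,
                         optimize=True).astype(x.data.dtype)

    def vjp_w(g):
        g4 = g.reshape(B, F1, F2, T)
        return np.einsum("bfct,bfgt->fgc", x.data, g4,
                         optimize=True).astype(w.data.dtype)

    return Tensor(y, [(x, vjp_x), (w, vjp_w)])


def batchnorm(x, gamma, beta, running_mean, running_var, training: bool,
              momentum: float = 0.1, eps: float = 1e-5,
              update_running: bool = True):
    """Batch normalization over all axes except axis 1 (the map axis).

    In training mode the batch statistics are used and ``running_mean`` /
    ``running_var`` (plain arrays) are updated in place with the biased
    batch variance; in eval mode the running statistics are used.
    ``update_running=False`` keeps batch-statistic normalization but leaves
    the running buffers untouched (used for target-domain passes, so the
    eval-time statistics are calibrated on source data only).
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    F = x.data.shape[1]
    axes = (0,) + tuple(range(2, x.data.ndim))
    gshape = (1, F) + (1,) * (x.data.ndim - 2)
    gm = gamma.data.reshape(gshape)
    bt = beta.data.reshape(gshape)

    if training:
        mu = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
        if update_running:
            running_mean *= (1.0 - momentum)
            running_mean += momentum * mu.reshape(F)
            running_var *= (1.0 - momentum)
            running_var += momentum * var.reshape(F)
    else:
        mu = running_mean.reshape(gshape).astype(x.data.dtype)
        var = running_var.reshape(gshape).astype(x.data.dtype)

    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    y = gm * xhat + bt
    nred = x.data.size // F

    def vjp_x(g):
        dxhat = g * gm
        if not training:
            return (dxhat * inv).astype(x.data.dtype)
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        return (inv * (dxhat - s1 / nred - xhat * s2 / nred)).astype(x.data.dtype)

    def vjp_gamma(g):
        return (g * xhat).sum(axis=axes).astype(gamma.data.dtype)

    def vjp_beta(g):
        return g.sum(axis=axes).astype(beta.data.dtype)

    return Tensor(y.astype(x.data.dtype),
                  [(x, vjp_x), (gamma, vjp_gamma), (beta, vjp_beta)])
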