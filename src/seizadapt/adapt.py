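"""Feature-based adversarial domain adaptation heads and losses.

Three objectives are supported, all sharing the structure

    min_{phi,F}  L_task(F(phi(X_S)), y_S)  +  lambda * L_domain
    max_D       -L_domain

where ``phi`` is the convolutional feature encoder, ``F`` the softmax
classifier, and ``D`` a domain discriminator trained to tell source
windows (domain label 0) from target windows (domain label 1):

* DANN — ``D`` sees the raw embedding phi(x).
* CDAN — ``D`` sees the multilinear conditioning map phi(x) (x) F(phi(x)),
  the flattened outer product of features and class probabilities.
* CDAN+E — CDAN with each example's discriminator loss re-weighted by
  ``1 + exp(-H(p))`` where H is the prediction entropy, emphasizing
  confident examples. Weights are detached from the classifier gradient.

The min-max is realized with a gradient-reversal node: the discriminator
minimizes binary cross-entropy, while the encoder (and, for CDAN, the
classifier) receives the reversed gradient scaled by lambda. All domain
losses use the batch-mean convention, so an uninformative discriminator
emitting probability 0.5 yields a domain loss of ln 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, autodiff as ad
from .nn.layers import Dense, ReLU
from .model import SeizureCNN

METHODS = ("none", "dann", "cdan", "cdan_e")


@dataclass
class DomainBatch:
    """One adversarial step's data: labeled source, unlabeled target."""

    xs: np.ndarray   # (n_s, 1, C, T)
    ys: np.ndarray   # (n_s,) in {0, 1}
    xt: np.ndarray   # (n_t, 1, C, T)

    def __post_init__(self):
        if len(self.xs) == 0 or len(self.xt) == 0:
            raise ValueError("source and target sides must both be non-empty")
        if self.xs.shape[2:] != self.xt.shape[2:]:
            raise ValueError("source and target must share (C, T)")


@dataclass
class DALossTerms:
    """Assembled loss pieces of one adversarial step."""

    task_loss: float
    domain_loss: float
    lambda_: float
    weights: np.ndarray
    total: Tensor = field(repr=False)


def grad_reverse(x, lambda_: float):
    """Identity forward; multiplies the upstream gradient by ``-lambda_``."""
    return ad.grad_reverse(x, lambda_)


def multilinear_map(features, probs):
    """Flattened outer product, feature-major: out[:, i*c + j] = f_i * p_j.

    Satisfies ||out||_2 = ||f||_2 * ||p||_2 row-wise.
    """
    f = features if isinstance(features, Tensor) else Tensor(np.asarray(features))
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs))
    n, d = f.data.shape
    c = p.data.shape[1]
    prod = ad.mul(ad.reshape(f, (n, d, 1)), ad.reshape(p, (n, 1, c)))
    return ad.reshape(prod, (n, d * c))


def entropy_weight(probs) -> np.ndarray:
    """Certainty weight ``1 + exp(-H(p))`` per example (natural log).

    H(one-hot) = 0 gives weight 2; the uniform distribution over two
    classes gives 1 + exp(-ln 2) = 1.5. The result is a plain array —
    detached, so no gradient flows from the weights into the classifier.
    """
    p = probs.data if isinstance(probs, Tensor) else np.asarray(probs)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=-1)
    return 1.0 + np.exp(-h)


def lambda_schedule(progress: float, gamma: float = 10.0) -> float:
    """The DANN ramp 2 / (1 + exp(-gamma * progress)) - 1 on [0, 1]."""
    if not 0.0 <= progress <= 1.0:
        raise ValueError("progress must lie in [0, 1]")
    return 2.0 / (1.0 + np.exp(-gamma * progress)) - 1.0


class Discriminator:
    """MLP domain discriminator: input -> hidden -> hidden -> 1 logit."""

    def __init__(self, input_dim: int, hidden: tuple[int, ...] = (128, 128),
                 seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        dims = (input_dim,) + tuple(hidden) + (1,)
        self.layers = [Dense(dims[i], dims[i + 1], rng, dtype)
                       for i in range(len(dims) - 1)]
        self._relu = ReLU()

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def logits(self, h) -> Tensor:
        if not isinstance(h, Tensor):
            h = Tensor(np.asarray(h, dtype=np.float32))
        if h.data.shape[1] != self.input_dim:
            raise ValueError(
                f"discriminator expects input dim {self.input_dim}, "
                f"got {h.data.shape[1]}")
        z = h
        for layer in self.layers[:-1]:
            z = self._relu(layer(z))
        return ad.reshape(self.layers[-1](z), (h.data.shape[0],))

    def predict_proba(self, h) -> np.ndarray:
        """P(target domain) per example, in (0, 1)."""
        z = self.logits(h if isinstance(h, Tensor) else
                        Tensor(np.asarray(h, dtype=np.float32))).data
        return 1.0 / (1.0 + np.exp(-z))


def _forward_two_domains(model: SeizureCNN, batch: DomainBatch, training,
                         rng):
    """Source and target pass through the shared encoder.

    The passes are separate (not one concatenated batch), each normalized
    by its own batch statistics, so a lambda=0 run performs exactly the
    parameter updates of supervised training on the source batches. Both
    passes contribute to the shared batch-norm running statistics — the
    same unlabeled-data usage a concatenated source+target batch would
    make — so eval-time normalization is calibrated on the source/target
    mixture.
    """
    out_s = model.forward(batch.xs, training=training, rng=rng,
                          update_stats=True)
    out_t = model.forward(batch.xt, training=training, rng=rng,
                          update_stats=True)
    return out_s, out_t


def _domain_targets(n_s: int, n_t: int) -> np.ndarray:
    return np.concatenate([np.zeros(n_s), np.ones(n_t)])


def dann_loss(model: SeizureCNN, discriminator: Discriminator,
              batch: DomainBatch, lambda_: float, training: bool = True,
              rng: np.random.Generator | None = None) -> DALossTerms:
    """Marginal adversarial alignment: D discriminates phi(x) by domain."""
    out_s, out_t = _forward_two_domains(model, batch, training, rng)
    task = ad.cross_entropy_logits(out_s.logits, batch.ys)
    feats = ad.concat([out_s.features, out_t.features], axis=0)
    z = discriminator.logits(grad_reverse(feats, lambda_))
    domain = ad.bce_logits(z, _domain_targets(len(batch.xs), len(batch.xt)))
    total = ad.add(task, domain)
    return DALossTerms(task_loss=task.item(), domain_loss=domain.item(),
                       lambda_=lambda_,
                       weights=np.ones(len(batch.xs) + len(batch.xt)),
                       total=total)


def cdan_loss(model: SeizureCNN, discriminator: Discriminator,
              batch: DomainBatch, lambda_: float,
              entropy_conditioning: bool = False, training: bool = True,
              rng: np.random.Generator | None = None) -> DALossTerms:
    """Conditional alignment: D sees phi(x) (x) F(phi(x)).

    With ``entropy_conditioning`` each example's discriminator loss term
    is scaled by its (detached) certainty weight.
    """
    c = model.config
    expected = c.feature_dim * c.N
    if discriminator.input_dim != expected:
        raise ValueError(
            f"CDAN discriminator needs input dim d*c = {expected}, "
            f"got {discriminator.input_dim}")
    out_s, out_t = _forward_two_domains(model, batch, training, rng)
    task = ad.cross_entropy_logits(out_s.logits, batch.ys)
    h_s = multilinear_map(out_s.features, out_s.probs)
    h_t = multilinear_map(out_t.features, out_t.probs)
    h = ad.concat([h_s, h_t], axis=0)
    z = discriminator.logits(grad_reverse(h, lambda_))
    if entropy_conditioning:
        weights = np.concatenate([entropy_weight(out_s.probs),
                                  entropy_weight(out_t.probs)])
    else:
        weights = np.ones(len(batch.xs) + len(batch.xt))
    domain = ad.bce_logits(z, _domain_targets(len(batch.xs), len(batch.xt)),
                           weights=weights)
    total = ad.add(task, domain)
    return DALossTerms(task_loss=task.item(), domain_loss=domain.item(),
                       lambda_=lambda_, weights=weights, total=total)


def build_discriminator(method: str, config, hidden=(128, 128),
                        seed: int = 0) -> Discriminator:
    """Discriminator sized for the method: d for DANN, d*c for CDAN."""
    if method == "dann":
        dim = config.feature_dim
    elif method in ("cdan", "cdan_e"):
        dim = config.feature_dim * config.N
    else:
        raise ValueError(f"no discriminator for method {method!r}")
    return Discriminator(dim, hidden=hidden, seed=seed)


def domain_loss_fn(method: str):
    """Return ``f(model, disc, batch, lambda_, training, rng) -> DALossTerms``."""
    if method == "dann":
        return dann_loss
    if method == "cdan":
        return lambda m, d, b, lam, training=True, rng=None: cdan_loss(
            m, d, b, lam, entropy_conditioning=False, training=training, rng=rng)
    if method == "cdan_e":
        return lambda m, d, b, lam, training=True, rng=None: cdan_loss(
            m, d, b, lam, entropy_conditioning=True, training=training, rng=rng)
    raise ValueError(f"unknown adaptation method {method!r}")
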