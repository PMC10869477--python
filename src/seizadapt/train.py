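"""Optimization loops for the supervised and domain-adversarial regimes.

Both regimes use ADAM (lr 0.005, betas 0.9/0.999 by default) and early
stopping on validation loss: training halts at ``max_epochs`` or once the
validation loss has failed to improve on its running best by more than
``min_delta`` for ``patience_epochs`` consecutive epochs, whichever comes
first, and the best-validation weights are restored. In the adapted
regime the monitored validation loss is computed on held-out *source*
windows — target labels are unavailable by definition and are not part of
the function signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import adapt
from .adapt import DomainBatch
from .model import SeizureCNN
from .nn import Adam, autodiff as ad
from .windows import WindowSet


@dataclass
class TrainConfig:
    lr: float = 0.005
    beta1: float = 0.9
    beta2: float = 0.999
    max_epochs: int = 500
    patience_epochs: int = 20
    batch_size: int = 64
    seed: int = 0
    adapt_method: str = "none"
    lambda_mode: str = "schedule"       # "schedule" or "constant"
    lambda_value: float = 1.0           # used when lambda_mode == "constant"
    lambda_gamma: float = 10.0
    min_delta: float = 1e-4
    disc_hidden: tuple[int, ...] = (128, 128)

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("betas must lie in (0, 1)")
        if self.patience_epochs >= self.max_epochs:
            raise ValueError("patience_epochs must be below max_epochs")
        if self.adapt_method not in adapt.METHODS:
            raise ValueError(f"adapt_method must be one of {adapt.METHODS}")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    domain_loss: list[float] = field(default_factory=list)
    stop_reason: str = ""
    epochs_run: int = 0
    best_epoch: int = -1
    best_val_loss: float = float("inf")


def _check_sets(train_set: WindowSet, val_set: WindowSet):
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("training and validation sets must be non-empty")
    n0, n1 = train_set.class_counts()
    if n0 == 0 or n1 == 0:
        raise ValueError("training set must contain both classes")


def evaluate_loss(model: SeizureCNN, ws: WindowSet,
                  batch_size: int = 256) -> tuple[float, float]:
    """Eval-mode mean cross-entropy and accuracy on a window set."""
    probs = model.predict_proba(ws.X, batch_size=batch_size)
    p1 = np.clip(probs[np.arange(len(ws)), ws.y], 1e-12, 1.0)
    loss = float(-np.log(p1).mean())
    acc = float((probs.argmax(axis=1) == ws.y).mean())
    return loss, acc


class _EarlyStopper:
    """No-improvement-for-``patience``-epochs rule with best-state snapshot."""

    def __init__(self, patience: int, min_delta: float):
        self.patience, self.min_delta = patience, min_delta
        self.best = float("inf")
        self.best_epoch = -1
        self.stale = 0

    def update(self, epoch: int, val_loss: float) -> tuple[bool, bool]:
        """Returns (improved, should_stop)."""
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.best_epoch = epoch
            self.stale = 0
            return True, False
        self.stale += 1
        return False, self.stale >= self.patience


def train_supervised(model: SeizureCNN, train_set: WindowSet,
                     val_set: WindowSet, config: TrainConfig
                     ) -> tuple[SeizureCNN, TrainHistory]:
    """Cross-entropy training with ADAM and validation early stopping."""
    _check_sets(train_set, val_set)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.lr, beta1=config.beta1,
               beta2=config.beta2)
    stopper = _EarlyStopper(config.patience_epochs, config.min_delta)
    hist = TrainHistory()
    best_state = model.state_dict()

    for epoch in range(config.max_epochs):
        losses, correct, seen = [], 0, 0
        for xb, yb in train_set.batches(config.batch_size, rng):
            out = model.forward(xb, training=True, rng=rng)
            loss = ad.cross_entropy_logits(out.logits, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            correct += int((out.probs.data.argmax(axis=1) == yb).sum())
            seen += len(yb)
        vloss, vacc = evaluate_loss(model, val_set)
        hist.train_loss.append(float(np.mean(losses)))
        hist.train_acc.append(correct / seen)
        hist.val_loss.append(vloss)
        hist.val_acc.append(vacc)
        hist.epochs_run = epoch + 1
        improved, stop = stopper.update(epoch, vloss)
        if improved:
            best_state = model.state_dict()
        if stop:
            hist.stop_reason = "early_stop"
            break
    else:
        hist.stop_reason = "max_epochs"
    hist.best_epoch = stopper.best_epoch
    hist.best_val_loss = stopper.best
    model.load_state(best_state)
    return model, hist


def train_adapted(model: SeizureCNN, source_train: WindowSet,
                  source_val: WindowSet, target_unlabeled: np.ndarray,
                  config: TrainConfig,
                  discriminator: adapt.Discriminator | None = None
                  ) -> tuple[SeizureCNN, TrainHistory]:
    """Adversarial training on labeled source + unlabeled target windows.

    ``target_unlabeled`` is an array of window tensors (n, C, T) — labels
    are not part of the interface. Each step pairs one source batch with
    one target batch (the smaller side cycles). Early stopping monitors
    the source validation loss.
    """
    if config.adapt_method == "none":
        logging.getLogger(__name__).info(
            "adapt_method='none': delegating to supervised training")
        return train_supervised(model, source_train, source_val, config)
    _check_sets(source_train, source_val)
    xt_all = np.asarray(target_unlabeled, dtype=np.float32)
    if xt_all.ndim != 3 or len(xt_all) == 0:
        raise ValueError("target_unlabeled must be a non-empty (n, C, T) array")

    rng = np.random.default_rng(config.seed)
    if discriminator is None:
        discriminator = adapt.build_discriminator(
            config.adapt_method, model.config, hidden=config.disc_hidden,
            seed=int(rng.integers(2 ** 31)))
    loss_fn = adapt.domain_loss_fn(config.adapt_method)
    opt = Adam(model.params() + discriminator.params(), lr=config.lr,
               beta1=config.beta1, beta2=config.beta2)
    stopper = _EarlyStopper(config.patience_epochs, config.min_delta)
    hist = TrainHistory()
    best_state = model.state_dict()

    steps_per_epoch = int(np.ceil(len(source_train) / config.batch_size))
    total_steps = max(config.max_epochs * steps_per_epoch, 1)
    step = 0
    t_order = rng.permutation(len(xt_all))
    t_pos = 0

    def next_target(n: int) -> np.ndarray:
        nonlocal t_order, t_pos
        out = []
        need = n
        while need > 0:
            if t_pos >= len(t_order):
                t_order = rng.permutation(len(xt_all))
                t_pos = 0
            take = min(need, len(t_order) - t_pos)
            out.append(xt_all[t_order[t_pos:t_pos + take]])
            t_pos += take
            need -= take
        return np.concatenate(out)[:, None, :, :]

    for epoch in range(config.max_epochs):
        tlosses, dlosses, correct, seen = [], [], 0, 0
        for xb, yb in source_train.batches(config.batch_size, rng):
            if config.lambda_mode == "constant":
                lam = config.lambda_value
            else:
                lam = adapt.lambda_schedule(step / total_steps,
                                            gamma=config.lambda_gamma)
            batch = DomainBatch(xs=xb, ys=yb, xt=next_target(len(xb)))
            terms = loss_fn(model, discriminator, batch, lam,
                            training=True, rng=rng)
            opt.zero_grad()
            terms.total.backward()
            opt.step()
            step += 1
            tlosses.append(terms.task_loss)
            dlosses.append(terms.domain_loss)
        vloss, vacc = evaluate_loss(model, source_val)
        hist.train_loss.append(float(np.mean(tlosses)))
        hist.domain_loss.append(float(np.mean(dlosses)))
        hist.val_loss.append(vloss)
        hist.val_acc.append(vacc)
        hist.epochs_run = epoch + 1
        improved, stop = stopper.update(epoch, vloss)
        if improved:
            best_state = model.state_dict()
        if stop:
            hist.stop_reason = "early_stop"
            break
    else:
        hist.stop_reason = "max_epochs"
    hist.best_epoch = stopper.best_epoch
    hist.best_val_loss = stopper.best
    model.load_state(best_state)
    return model, hist
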