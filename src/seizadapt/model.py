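"""The compact three-block convolutional EEG classifier.

The network mirrors the filter-bank-CSP intuition: a first bank of F1
temporal filters (kernel (1, 128), linear, no bias) learns frequency
components; a depthwise (C, 1) stage with multiplier F2 learns spatial
filters over the C electrodes per temporal map; after pooling, the F2*F1
maps are stacked into the spatial axis of a single-map tensor and a third
convolution with F3 kernels (1, 64) extracts features shared across those
maps, so its weight count is 64*F3 rather than 64*F3*F2*F1. A dense
softmax head produces the two class probabilities (inter-ictal vs
pre-ictal). Convolutions carry no bias; batch normalization supplies the
affine shift.

Per-layer trainable weights:

====================  =================
2D convolution        128 * F1
batch norm            2 * F1
depthwise conv        C * F2 * F1
batch norm            2 * F2 * F1
2D convolution        64 * F3
batch norm            2 * F3
dense                 (F3*F2*F1*(T//256) + 1) * N
====================  =================

The flattened embedding phi(x) of dimension F3*F2*F1*(T'//16), with
T' = T//16, is exposed alongside the probabilities for the adversarial
adaptation heads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, autodiff as ad
from .nn.layers import (AvgPoolTime, BatchNorm, ConvTemporal, Dense,
                        DepthwiseSpatial, Dropout, ReLU)

TEMPORAL_KERNEL = 128
FEATURE_KERNEL = 64


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    C
        number of EEG channels.
    T
        samples per window (window seconds x sampling rate).
    F1, F2, F3
        temporal-filter count, depthwise multiplier (spatial filters per
        temporal filter), feature-filter count.
    N
        number of classes (binary task: 2).
    dropout_p
        dropout probability after each pooling stage.
    pool
        temporal pooling factor applied twice (default 16).
    """

    C: int
    T: int
    F1: int = 8
    F2: int = 2
    F3: int = 16
    N: int = 2
    dropout_p: float = 0.25
    pool: int = 16
    pad_mode: str = "same"

    def __post_init__(self):
        if min(self.F1, self.F2, self.F3) < 1:
            raise ValueError("F1, F2, F3 must all be >= 1")
        if self.N != 2:
            raise ValueError("this classifier is binary (N must be 2)")
        if self.pad_mode == "same":
            if self.T % self.pool or (self.T // self.pool) % self.pool:
                raise ValueError(
                    f"T={self.T} must be divisible by pool={self.pool} at both "
                    f"pooling stages (T//pool={self.T // self.pool})")

    @property
    def t_prime(self) -> int:
        return self.T // self.pool

    @property
    def feature_dim(self) -> int:
        return self.F3 * self.F2 * self.F1 * (self.t_prime // self.pool)


@dataclass
class ForwardOutput:
    """features = flattened embedding phi(x); probs = softmax output F(phi(x))."""

    features: Tensor
    logits: Tensor
    probs: Tensor


class SeizureCNN:
    """The classifier; ``encode`` yields phi(x), ``forward`` adds the head."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.conv1 = ConvTemporal(c.F1, TEMPORAL_KERNEL, rng, dtype,
                                  pad_mode=c.pad_mode)
        self.bn1 = BatchNorm(c.F1, dtype)
        self.depthwise = DepthwiseSpatial(c.F1, c.F2, c.C, rng, dtype)
        self.bn2 = BatchNorm(c.F2 * c.F1, dtype)
        self.relu1 = ReLU()
        self.pool1 = AvgPoolTime(c.pool)
        self.drop1 = Dropout(c.dropout_p)
        self.conv3 = ConvTemporal(c.F3, FEATURE_KERNEL, rng, dtype,
                                  pad_mode=c.pad_mode)
        self.bn3 = BatchNorm(c.F3, dtype)
        self.relu2 = ReLU()
        self.pool2 = AvgPoolTime(c.pool)
        self.drop2 = Dropout(c.dropout_p)
        self.dense = Dense(c.feature_dim, c.N, rng, dtype)
        self._layers = [self.conv1, self.bn1, self.depthwise, self.bn2,
                        self.relu1, self.pool1, self.drop1, self.conv3,
                        self.bn3, self.relu2, self.pool2, self.drop2,
                        self.dense]

    # -- parameters ---------------------------------------------------------

    def params(self):
        out = []
        for layer in self._layers:
            out.extend(layer.params())
        return out

    def param_counts(self) -> dict[str, int]:
        """Framework-reported trainable weight count per parameterized layer."""
        return {
            "conv_temporal": self.conv1.param_count(),
            "batchnorm_1": self.bn1.param_count(),
            "depthwise": self.depthwise.param_count(),
            "batchnorm_2": self.bn2.param_count(),
            "conv_feature": self.conv3.param_count(),
            "batchnorm_3": self.bn3.param_count(),
            "dense": self.dense.param_count(),
        }

    def state_dict(self) -> dict:
        return {f"layer{i}": layer.state_dict()
                for i, layer in enumerate(self._layers)}

    def load_state(self, state: dict):
        for i, layer in enumerate(self._layers):
            layer.load_state(state.get(f"layer{i}", {}))

    # -- forward ------------------------------------------------------------

    def _check_batch(self, x: np.ndarray):
        c = self.config
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2:] != (c.C, c.T):
            raise ValueError(
                f"expected batch of shape (n, 1, {c.C}, {c.T}), got {x.shape}")

    def encode(self, x, training: bool = False,
               rng: np.random.Generator | None = None,
               update_stats: bool = True) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        self._check_batch(x.data)
        c = self.config
        n = x.data.shape[0]
        h = self.conv1(x)                                # (n, F1, C, T)
        h = self.bn1(h, training, update_stats)
        h = self.depthwise(h, training)                  # (n, F2*F1, 1, T)
        h = self.bn2(h, training, update_stats)
        h = self.relu1(h)
        h = self.pool1(h)                                # (n, F2*F1, 1, T//16)
        h = self.drop1(h, training, rng)
        # the F2*F1 maps become the spatial axis of a single-map tensor
        h = ad.reshape(h, (n, 1, c.F2 * c.F1, c.t_prime))
        h = self.conv3(h)                                # (n, F3, F2*F1, T')
        h = self.bn3(h, training, update_stats)
        h = self.relu2(h)
        h = self.pool2(h)                                # (n, F3, F2*F1, T'//16)
        h = self.drop2(h, training, rng)
        return ad.reshape(h, (n, c.feature_dim))

    def forward(self, x, training: bool = False,
                rng: np.random.Generator | None = None,
                update_stats: bool = True) -> ForwardOutput:
        feats = self.encode(x, training, rng, update_stats)
        logits = self.dense(feats, training)
        probs = ad.softmax(logits)
        return ForwardOutput(features=feats, logits=logits, probs=probs)

    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        """Deterministic (eval-mode) class probabilities, batched."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward(x[i:i + batch_size]).probs.data)
        return np.concatenate(out, axis=0)


def build_model(config: ModelConfig, seed: int = 0) -> SeizureCNN:
    """Validate the configuration and construct the classifier."""
    return SeizureCNN(config, seed=seed)


def expected_param_counts(config: ModelConfig) -> dict[str, int]:
    """Closed-form per-layer weight counts of the architecture table."""
    c = config
    return {
        "conv_temporal": TEMPORAL_KERNEL * c.F1,
        "batchnorm_1": 2 * c.F1,
        "depthwise": c.C * c.F2 * c.F1,
        "batchnorm_2": 2 * c.F2 * c.F1,
        "conv_feature": FEATURE_KERNEL * c.F3,
        "batchnorm_3": 2 * c.F3,
        "dense": (c.feature_dim + 1) * c.N,
    }


def save_checkpoint(model: SeizureCNN, path, meta: dict | None = None) -> None:
    """Model weights + config (+ optional metadata sidecar) in one archive."""
    import json
    from dataclasses import asdict

    flat = {}
    for lname, ldict in model.state_dict().items():
        for pname, arr in ldict.items():
            flat[f"{lname}/{pname}"] = arr
    np.savez_compressed(path, __config__=json.dumps(asdict(model.config)),
                        __meta__=json.dumps(meta or {}), **flat)


def load_checkpoint(path) -> tuple["SeizureCNN", dict]:
    import json

    with np.load(path, allow_pickle=False) as z:
        cfg = ModelConfig(**json.loads(str(z["__config__"])))
        meta = json.loads(str(z["__meta__"]))
        model = SeizureCNN(cfg)
        state: dict[str, dict] = {}
        for key in z.files:
            if key.startswith("__"):
                continue
            lname, pname = key.split("/", 1)
            state.setdefault(lname, {})[pname] = z[key]
        model.load_state(state)
    return model, meta


def layer_output_shapes(config: ModelConfig) -> list[tuple[str, tuple]]:
    """Symbolic per-stage output shapes (excluding the batch axis)."""
    c = config
    tp = c.t_prime
    return [
        ("input", (1, c.C, c.T)),
        ("conv_temporal", (c.F1, c.C, c.T)),
        ("batchnorm_1", (c.F1, c.C, c.T)),
        ("depthwise", (c.F2 * c.F1, 1, c.T)),
        ("batchnorm_2", (c.F2 * c.F1, 1, c.T)),
        ("relu_1", (c.F2 * c.F1, 1, c.T)),
        ("avgpool_1", (c.F2 * c.F1, 1, tp)),
        ("dropout_1", (c.F2 * c.F1, 1, tp)),
        ("conv_feature", (c.F3, c.F2 * c.F1, tp)),
        ("batchnorm_3", (c.F3, c.F2 * c.F1, tp)),
        ("relu_2", (c.F3, c.F2 * c.F1, tp)),
        ("avgpool_2", (c.F3, c.F2 * c.F1, tp // c.pool)),
        ("dropout_2", (c.F3, c.F2 * c.F1, tp // c.pool)),
        ("flatten", (c.feature_dim,)),
        ("dense", (c.N,)),
    ]
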