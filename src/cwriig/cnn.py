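"""The six-channel tumor-classification CNN and its training protocol.

Architecture (input 224 x 224 x 6):

====================  ===========  ======  ==============
layer                 kernel       stride  output
====================  ===========  ======  ==============
Conv 1 + ReLU         6 x 6 x 64   2       112 x 112 x 64
MaxPool               2 x 2        1       112 x 112 x 64
Conv 2 + ReLU         5 x 5 x 46   2       56 x 56 x 46
MaxPool               2 x 2        1       56 x 56 x 46
Conv 3 + ReLU         4 x 4 x 32   2       28 x 28 x 32
MaxPool               2 x 2        1       28 x 28 x 32
Conv 4 + ReLU         3 x 3 x 16   1       28 x 28 x 16
MaxPool               2 x 2        1       28 x 28 x 16
pooling (see below)                        28 x 28 x 16
FC + ReLU                                  16
FC                                         2
combined activation                        2
====================  ===========  ======  ==============

The reference layer table prints an unreduced 28 x 28 x 16 output for its
"global average pooling" row, and only the flattened reading (an
extent-preserving 2 x 2 spatial average whose 12544 values feed the first
FC) reproduces the ~316k parameter budget, so that is the default
(``gap_mode="flatten"``; direct count 316,496).  A strict global average
(collapse to 16 values) is available with ``gap_mode="strict"``.

The output activation adds the sigmoid of each logit to its softmax
probability: components lie in (0, 2), and the sigmoid term breaks exact
softmax ties, which is the stated reason for combining the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .nn import (
    Adam,
    AvgPool2x2,
    Conv2d,
    Dense,
    Flatten,
    GlobalAvgPool,
    MaxPool2x2,
    ReLU,
    Sequential,
)
from .parametric import STACK_SIZE, SubbandStack

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "build_network",
    "combined_activation",
    "combined_ce_loss",
    "predict_logits",
    "predict_labels",
    "train",
    "extract_features",
    "stacks_to_arrays",
    "LABELS",
]

LABELS = ("benign", "malignant")  # index 1 (malignant) is the positive class

#: (kernel, stride, pad, out_channels) per conv block, in order.
_CONV_BLOCKS = ((6, 2, 2, 64), (5, 2, 2, 46), (4, 2, 1, 32), (3, 1, 1, 16))


@dataclass(frozen=True)
class NetworkSpec:
    """Construction settings; defaults reproduce the reference layer table."""

    in_channels: int = 6
    input_size: int = STACK_SIZE
    conv_blocks: tuple = _CONV_BLOCKS
    fc_width: int = 16
    n_classes: int = 2
    gap_mode: str = "flatten"  # or "strict"

    def __post_init__(self) -> None:
        if self.gap_mode not in ("flatten", "strict"):
            raise ValueError(f"gap_mode must be 'flatten' or 'strict', got {self.gap_mode!r}")


@dataclass
class TrainingConfig:
    """Optimization settings (defaults follow the reference protocol).

    ``warmup_iterations`` ramps the Adam step size linearly from zero;
    with ReLU stacks this size, full-size steps from the very first
    iteration can kill every unit before the loss surface is explored
    (dead-ReLU collapse), and a short warmup prevents it.
    """

    batch_size: int = 60
    learning_rate: float = 0.01
    iterations: int = 4000
    warmup_iterations: int = 0
    test_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.warmup_iterations < 0:
            raise ValueError("warmup_iterations must be >= 0")


def build_network(spec: NetworkSpec = NetworkSpec(), seed: int = 0) -> Sequential:
    """Construct the network with seeded He-initialized weights."""
    rng = np.random.default_rng(seed)
    layers: list = []
    shape = (spec.input_size, spec.input_size, spec.in_channels)
    c_in = spec.in_channels
    for bi, (k, s, p, c_out) in enumerate(spec.conv_blocks):
        layers += [Conv2d(c_in, c_out, k, s, p, rng, need_input_grad=bi > 0),
                   ReLU(), MaxPool2x2()]
        c_in = c_out
    if spec.gap_mode == "flatten":
        layers += [AvgPool2x2(), Flatten()]
    else:
        layers += [GlobalAvgPool()]
    cur = shape
    for l in layers:
        cur = l.out_shape(cur)
    layers += [Dense(int(np.prod(cur)), spec.fc_width, rng), ReLU(),
               Dense(spec.fc_width, spec.n_classes, rng)]
    net = Sequential(layers, shape)
    net.feature_layer_index = len(layers) - 2  # ReLU after the first FC
    net.spec = spec
    return net


# ------------------------------------------------------------- activation

def combined_activation(z: np.ndarray) -> np.ndarray:
    """softmax(z) + sigmoid(z) per component; values in (0, 2)."""
    z = np.asarray(z, dtype=np.float64)
    zz = np.atleast_2d(z)
    zs = zz - zz.max(axis=1, keepdims=True)
    e = np.exp(zs)
    soft = e / e.sum(axis=1, keepdims=True)
    out = soft + expit(zz)
    return out.reshape(z.shape)


def combined_ce_loss(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Cross-entropy on renormalized combined-activation scores, with gradient.

    The combined scores c = softmax(z) + sigmoid(z) sum to k/... more than 1;
    they are renormalized to probabilities p = c / sum(c) before the
    negative log-likelihood.
    """
    z = np.asarray(z, dtype=np.float64)
    n, k = z.shape
    zs = z - z.max(axis=1, keepdims=True)
    e = np.exp(zs)
    s = e / e.sum(axis=1, keepdims=True)
    g = expit(z)
    c = s + g
    total = c.sum(axis=1, keepdims=True)
    p = c / total
    idx = (np.arange(n), y)
    loss = float(-np.mean(np.log(np.maximum(p[idx], 1e-300))))
    # dL/dc_i = 1/total - delta_{iy}/c_y   (per sample, before the 1/n mean)
    t = 1.0 / total - np.where(
        np.arange(k)[None, :] == y[:, None], 1.0 / np.maximum(c, 1e-300), 0.0
    )
    ts = (t * s).sum(axis=1, keepdims=True)
    dz = s * (t - ts) + t * g * (1.0 - g)
    return loss, (dz / n).astype(np.float32)


# --------------------------------------------------------------- training

def stacks_to_arrays(samples: list[SubbandStack]) -> tuple[np.ndarray, np.ndarray]:
    """SubbandStacks -> (X NHWC float32, y int labels)."""
    if not samples:
        raise ValueError("empty sample list")
    X = np.empty((len(samples), STACK_SIZE, STACK_SIZE, 6), dtype=np.float32)
    y = np.empty(len(samples), dtype=np.int64)
    for i, s in enumerate(samples):
        if s.label not in LABELS:
            raise ValueError(f"sample {s.source_id!r} has label {s.label!r}")
        X[i] = s.channels.transpose(1, 2, 0)
        y[i] = LABELS.index(s.label)
    return X, y


def train(
    network: Sequential,
    train_samples,
    config: TrainingConfig,
) -> list[float]:
    """Train with Adam on shuffled mini-batches; returns the loss trace.

    ``train_samples`` is either a list of labelled SubbandStacks or an
    ``(X, y)`` pair (NHWC float array, integer labels).
    """
    if isinstance(train_samples, tuple):
        X, y = train_samples
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
    else:
        X, y = stacks_to_arrays(list(train_samples))
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least 2 classes")
    rng = np.random.default_rng(config.seed)
    opt = Adam(network.params, lr=config.learning_rate)
    order = rng.permutation(X.shape[0])
    pos = 0
    trace: list[float] = []
    for it in range(config.iterations):
        if config.warmup_iterations:
            opt.lr = config.learning_rate * min(1.0, (it + 1) / config.warmup_iterations)
        take = min(config.batch_size, X.shape[0])
        if pos + take > order.size:
            order = rng.permutation(X.shape[0])
            pos = 0
        idx = order[pos:pos + take]
        pos += take
        logits = network.forward(X[idx], train=True)
        loss, dz = combined_ce_loss(logits, y[idx])
        network.backward(dz)
        opt.step(network.grads)
        trace.append(loss)
    return trace


def predict_logits(network: Sequential, X: np.ndarray, batch: int = 50) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    return np.concatenate([network.forward(X[i:i + batch]) for i in range(0, X.shape[0], batch)])


def predict_labels(network: Sequential, X: np.ndarray) -> np.ndarray:
    """Predicted class = argmax of the combined-activation scores."""
    return np.argmax(combined_activation(predict_logits(network, X)), axis=1)


def extract_features(network: Sequential, samples, batch: int = 50) -> np.ndarray:
    """16-length pooled feature vector per sample (ReLU of the first FC)."""
    if isinstance(samples, np.ndarray):
        X = samples.astype(np.float32)
    else:
        X, _ = stacks_to_arrays(list(samples))
    feats = [
        network.forward(X[i:i + batch], return_hidden=network.feature_layer_index)
        for i in range(0, X.shape[0], batch)
    ]
    return np.concatenate(feats)
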