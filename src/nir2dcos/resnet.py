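"""A 12-layer residual CNN for 2DCOS raster classification.

Architecture: one stem convolution (BatchNorm + ReLU), then a fixed
sequence of four identity blocks and two conv blocks, then global
average pooling → flatten → one fully-connected layer.  An identity
block keeps shapes and adds its input to the two-convolution main path
(it learns the residual F(x) = H(x) − x); a conv block halves the
spatial size and doubles the width, reconciling shapes through a 1×1
shortcut convolution.

Depth accounting: stem conv (1) + 4 identity blocks × 2 convs (8) +
2 conv blocks × 1 main-path conv (2) + fully-connected (1) = 12.
Shortcut 1×1 convolutions, pooling and flatten carry no counted weight
layers.

Training follows the reference recipe: plain stochastic gradient
descent (momentum optional, off by default), cross-entropy loss,
learning rate 0.01, weight-decay λ = 1e-4, batch size 16.  The
exponential curve smoothing (0.6) is display-only and never touches
stored metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix as _sk_confusion

from .nn import (BatchNorm2d, Conv2d, GlobalAvgPool, Linear, ReLU, Sequential,
                 SoftmaxCrossEntropy, sgd_step)

__all__ = ["ResNetSpec", "TrainConfig", "ResNet", "ResNetClassifier",
           "build_resnet", "evaluate", "smooth_curve"]


@dataclass(frozen=True)
class ResNetSpec:
    """Structural plan of the network.

    ``block_plan`` lists the residual blocks in order ("identity" or
    "conv"); each conv block halves the spatial size and multiplies the
    width by ``width_multiplier``.  The default plan — two identity
    blocks, a conv block, an identity block, a conv block, an identity
    block — contains four identity and two conv blocks.
    """

    stem_channels: int = 16
    block_plan: tuple[str, ...] = ("identity", "identity", "conv",
                                   "identity", "conv", "identity")
    width_multiplier: int = 2
    kernel: int = 3
    input_size: int = 64

    def counted_depth(self) -> int:
        """Weight-layer count: stem + 2 per identity block + 1 main-path
        conv per conv block + the fully-connected head."""
        n_id = sum(b == "identity" for b in self.block_plan)
        n_conv = sum(b == "conv" for b in self.block_plan)
        return 1 + 2 * n_id + n_conv + 1

    def final_width(self) -> int:
        w = self.stem_channels
        for b in self.block_plan:
            if b == "conv":
                w *= self.width_multiplier
        return w


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults are the reference values)."""

    learning_rate: float = 0.01
    weight_decay: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 30
    momentum: float = 0.0
    curve_smoothing: float = 0.6   # display only
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("learning_rate, batch_size, max_epochs must be > 0")
        if self.weight_decay < 0 or self.momentum < 0:
            raise ValueError("weight_decay and momentum must be >= 0")


class _IdentityBlock:
    """x + F(x) with F = conv-bn-relu-conv-bn; output shape = input shape."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, kernel, 1, rng)
        self.bn1 = BatchNorm2d(channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, kernel, 1, rng)
        self.bn2 = BatchNorm2d(channels)
        self.relu_out = ReLU()
        self._main = Sequential(self.conv1, self.bn1, self.relu1,
                                self.conv2, self.bn2)

    @property
    def params(self):
        return self._main.params

    @property
    def decayed_params(self):
        return self._main.decayed_params

    def forward(self, x, train=True):
        return self.relu_out.forward(self._main.forward(x, train) + x, train)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        return self._main.backward(g) + g


class _ConvBlock:
    """Downsampling residual block: 3×3 stride-2 main conv + BN, added to a
    1×1 stride-2 shortcut conv + BN."""

    def __init__(self, cin: int, cout: int, kernel: int,
                 rng: np.random.Generator):
        self.conv_main = Conv2d(cin, cout, kernel, 2, rng)
        self.bn_main = BatchNorm2d(cout)
        self.conv_short = Conv2d(cin, cout, 1, 2, rng)
        self.bn_short = BatchNorm2d(cout)
        self.relu_out = ReLU()
        self._main = Sequential(self.conv_main, self.bn_main)
        self._short = Sequential(self.conv_short, self.bn_short)

    @property
    def params(self):
        return self._main.params + self._short.params

    @property
    def decayed_params(self):
        return self._main.decayed_params + self._short.decayed_params

    def forward(self, x, train=True):
        return self.relu_out.forward(
            self._main.forward(x, train) + self._short.forward(x, train), train)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        return self._main.backward(g) + self._short.backward(g)


class ResNet:
    """The assembled network: forward maps (N, 3, H, W) → (N, n_classes)."""

    def __init__(self, n_classes: int, spec: ResNetSpec,
                 rng: np.random.Generator):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.spec = spec
        blocks: list = []
        width = spec.stem_channels
        for kind in spec.block_plan:
            if kind == "identity":
                blocks.append(_IdentityBlock(width, spec.kernel, rng))
            elif kind == "conv":
                blocks.append(_ConvBlock(width, width * spec.width_multiplier,
                                         spec.kernel, rng))
                width *= spec.width_multiplier
            else:
                raise ValueError(f"unknown block kind {kind!r}")
        self.stem = Sequential(Conv2d(3, spec.stem_channels, spec.kernel, 1, rng),
                               BatchNorm2d(spec.stem_channels), ReLU())
        self.blocks = blocks
        self.pool = GlobalAvgPool()
        self.fc = Linear(width, n_classes, rng)
        self.n_classes = n_classes

    @property
    def params(self):
        out = list(self.stem.params)
        for b in self.blocks:
            out.extend(b.params)
        out.extend(self.fc.params)
        return out

    @property
    def decayed_params(self):
        out = list(self.stem.decayed_params)
        for b in self.blocks:
            out.extend(b.decayed_params)
        out.extend(self.fc.decayed_params)
        return out

    def counted_depth(self) -> int:
        return self.spec.counted_depth()

    def _primitive_layers(self) -> list:
        layers = list(self.stem.layers)
        for b in self.blocks:
            layers.extend(b._main.layers)
            if isinstance(b, _ConvBlock):
                layers.extend(b._short.layers)
        layers.append(self.fc)
        return layers

    _STATE_FIELDS = ("weight", "bias", "gamma", "beta", "running_mean",
                     "running_var")

    def state_arrays(self) -> list[np.ndarray]:
        """All learned/accumulated arrays in deterministic order."""
        out = []
        for layer in self._primitive_layers():
            for name in self._STATE_FIELDS:
                if hasattr(layer, name):
                    out.append(getattr(layer, name))
        return out

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        targets = self.state_arrays()
        if len(arrays) != len(targets):
            raise ValueError("checkpoint does not match this architecture")
        for dst, src in zip(targets, arrays):
            if dst.shape != src.shape:
                raise ValueError("checkpoint shape mismatch "
                                 f"{src.shape} vs {dst.shape}")
            dst[...] = src

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.stem.forward(x, train)
        for b in self.blocks:
            h = b.forward(h, train)
        return self.fc.forward(self.pool.forward(h, train), train)

    def backward(self, grad: np.ndarray) -> None:
        g = self.pool.backward(self.fc.backward(grad))
        for b in reversed(self.blocks):
            g = b.backward(g)
        self.stem.backward(g)


def build_resnet(n_classes: int, spec: ResNetSpec = ResNetSpec(),
                 seed: int = 0) -> ResNet:
    """Construct the network with seeded initialization."""
    return ResNet(n_classes, spec, np.random.default_rng(seed))


def smooth_curve(values: Sequence[float], smoothing: float = 0.6) -> np.ndarray:
    """Exponential running smoothing for plotted curves (display only)."""
    out = np.empty(len(values))
    acc = None
    for i, v in enumerate(values):
        acc = v if acc is None else smoothing * acc + (1 - smoothing) * v
        out[i] = acc
    return out


class ResNetClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style front end: SGD training of the 12-layer residual CNN.

    ``fit(X, y)`` expects images as (N, H, W, 3) uint8 (or floats in
    [0, 255]); pass ``X_val, y_val`` to record per-epoch test metrics in
    ``trace_``.  Training is deterministic given ``random_state``
    (initialization and shuffling draw from one seeded stream).

    Parameters mirror :class:`TrainConfig`; architecture knobs come from
    ``spec``.  ``early_stop=True`` halts once training accuracy is 1.0
    and the training loss is below ``early_stop_loss``.
    """

    def __init__(self, spec: ResNetSpec = ResNetSpec(),
                 learning_rate: float = 0.01, weight_decay: float = 1e-4,
                 batch_size: int = 16, max_epochs: int = 30,
                 momentum: float = 0.0, early_stop: bool = False,
                 early_stop_loss: float = 1e-3, random_state: int = 0,
                 verbose: int = 0):
        self.spec = spec
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.momentum = momentum
        self.early_stop = early_stop
        self.early_stop_loss = early_stop_loss
        self.random_state = random_state
        self.verbose = verbose

    @staticmethod
    def _prep(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("expected images of shape (N, H, W, 3)")
        return (X.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)

    def fit(self, X, y, X_val=None, y_val=None):
        import warnings

        Xn = self._prep(X)
        y = np.asarray(y)
        self.classes_ = np.array(sorted(pd.unique(y).tolist()))
        class_idx = {c: i for i, c in enumerate(self.classes_)}
        t = np.array([class_idx[c] for c in y])
        rng = np.random.default_rng(self.random_state)
        self.network_ = ResNet(len(self.classes_), self.spec, rng)
        loss_fn = SoftmaxCrossEntropy()
        n = Xn.shape[0]
        batch = self.batch_size
        if batch > n:
            warnings.warn(f"batch_size {batch} > train size {n}; using {n}")
            batch = n
        velocities: dict = {}
        rows = []
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n)
            losses, hits = [], 0
            for start in range(0, n, batch):
                sel = order[start:start + batch]
                logits = self.network_.forward(Xn[sel], train=True)
                loss = loss_fn.forward(logits, t[sel])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch} "
                        f"(batch starting {start}); consider a lower "
                        f"learning rate")
                losses.append(loss * len(sel))
                hits += int((np.argmax(logits, axis=1) == t[sel]).sum())
                self.network_.backward(loss_fn.backward())
                sgd_step(self.network_.params, self.network_.decayed_params,
                         self.learning_rate, self.weight_decay,
                         self.momentum, velocities)
            row = {"epoch": epoch, "train_loss": sum(losses) / n,
                   "train_acc": hits / n}
            if X_val is not None:
                val_loss, val_acc = self._eval_loss(X_val, y_val)
                row.update(test_loss=val_loss, test_acc=val_acc)
            rows.append(row)
            if self.verbose:
                print(f"epoch {epoch:3d}  " +
                      "  ".join(f"{k}={v:.4f}" for k, v in row.items()
                                if k != "epoch"))
            if (self.early_stop and row["train_acc"] == 1.0
                    and row["train_loss"] < self.early_stop_loss):
                break
        self.trace_ = pd.DataFrame(rows)
        return self

    def _eval_loss(self, X, y) -> tuple[float, float]:
        logits = self._logits(X)
        t = np.searchsorted(self.classes_, np.asarray(y))
        loss = SoftmaxCrossEntropy().forward(logits, t)
        acc = float((np.argmax(logits, axis=1) == t).mean())
        return loss, acc

    def _logits(self, X, batch: int = 64) -> np.ndarray:
        Xn = self._prep(X)
        chunks = [self.network_.forward(Xn[i:i + batch], train=False)
                  for i in range(0, Xn.shape[0], batch)]
        return np.concatenate(chunks)

    def decision_function(self, X) -> np.ndarray:
        return self._logits(X)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self._logits(X), axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        z = self._logits(X)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    # -- checkpointing -----------------------------------------------------

    def save(self, path) -> None:
        """Write a fitted model (architecture + weights + classes) as npz."""
        import dataclasses
        import json

        meta = {"classes": list(map(str, self.classes_)),
                "spec": dataclasses.asdict(self.network_.spec)}
        np.savez(path,
                 meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **{f"arr{i}": a
                    for i, a in enumerate(self.network_.state_arrays())})

    @classmethod
    def load(cls, path) -> "ResNetClassifier":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            arrays = [data[f"arr{i}"] for i in range(len(data.files) - 1)]
        spec = ResNetSpec(**{**meta["spec"],
                             "block_plan": tuple(meta["spec"]["block_plan"])})
        clf = cls(spec=spec)
        clf.classes_ = np.array(meta["classes"])
        clf.network_ = build_resnet(len(clf.classes_), spec)
        clf.network_.load_state_arrays(arrays)
        return clf


def evaluate(clf: ResNetClassifier, X, y) -> tuple[np.ndarray, np.ndarray, float]:
    """Confusion matrices (raw counts and row-normalized) plus accuracy."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty evaluation set")
    pred = clf.predict(X)
    cm = _sk_confusion(y, pred, labels=clf.classes_)
    with np.errstate(invalid="ignore"):
        row_norm = cm / cm.sum(axis=1, keepdims=True)
    acc = float(np.trace(cm) / cm.sum())
    return cm, row_norm, acc
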