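"""Compact MobileNetV3-style classifier for the three severity classes.

The architecture is the bneck (inverted residual) stack: each block expands
with a 1×1 convolution, filters with a depthwise k×k convolution (stride 1 or
2), optionally re-weights channels with a squeeze-excitation unit, and
projects back down with a *linear* 1×1 convolution; the identity skip is
active exactly when stride is 1 and input width equals output width.
Activations are ReLU or h-swish, h-swish(x) = x·ReLU6(x+3)/6.

The default schedule is a reduced 6-block variant of MobileNetV3-Small at
width multiplier 0.5 — chosen so that CPU-scale training on a few hundred
slices finishes in minutes; the full small schedule is one config away.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .nn import h_swish

__all__ = [
    "BneckSpec",
    "ModelConfig",
    "REDUCED_SCHEDULE",
    "SMALL_SCHEDULE",
    "h_swish",
    "make_divisible",
    "Bneck",
    "MobileNetV3",
    "build_model",
    "train_classifier",
    "predict",
]


@dataclass(frozen=True)
class BneckSpec:
    in_channels: int
    expand_channels: int
    out_channels: int
    kernel: int = 3
    stride: int = 1
    use_se: bool = False
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.kernel not in (3, 5):
            raise ValueError("kernel must be 3 or 5")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.activation not in ("relu", "hswish"):
            raise ValueError("activation must be 'relu' or 'hswish'")

    @property
    def has_skip(self) -> bool:
        return self.stride == 1 and self.in_channels == self.out_channels


# Reduced 6-block schedule (pre-width-multiplier channel counts).
REDUCED_SCHEDULE: tuple[BneckSpec, ...] = (
    BneckSpec(16, 16, 16, 3, 2, True, "relu"),
    BneckSpec(16, 72, 24, 3, 2, False, "relu"),
    BneckSpec(24, 88, 24, 3, 1, False, "relu"),
    BneckSpec(24, 96, 40, 5, 2, True, "hswish"),
    BneckSpec(40, 240, 40, 5, 1, True, "hswish"),
    BneckSpec(40, 120, 48, 5, 1, True, "hswish"),
)

# Full MobileNetV3-Small bneck schedule for when more capacity is wanted.
SMALL_SCHEDULE: tuple[BneckSpec, ...] = REDUCED_SCHEDULE + (
    BneckSpec(48, 144, 48, 5, 1, True, "hswish"),
    BneckSpec(48, 288, 96, 5, 2, True, "hswish"),
    BneckSpec(96, 576, 96, 5, 1, True, "hswish"),
    BneckSpec(96, 576, 96, 5, 1, True, "hswish"),
)


@dataclass
class ModelConfig:
    bneck_specs: tuple[BneckSpec, ...] = REDUCED_SCHEDULE
    width_multiplier: float = 0.5
    n_classes: int = 3
    input_channels: int = 1
    dropout: float = 0.2
    stem_channels: int = 16
    last_channels: int = 128
    use_batchnorm: bool = True
    se_reduction: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0.25 <= self.width_multiplier <= 1.0:
            raise ValueError("width_multiplier must lie in [0.25, 1.0]")


def make_divisible(v: float, divisor: int = 8, min_value: int = 8) -> int:
    """Round a scaled channel count to a multiple of `divisor` (min 8)."""
    new_v = max(min_value, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


def _activation(name: str) -> nn.Module:
    return nn.ReLU() if name == "relu" else nn.HSwish()


class _SEUnit(nn.Module):
    """Squeeze-excitation with hard-sigmoid gate."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        hidden = make_divisible(channels / reduction, 8)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)
        self._cache = None

    def forward(self, x, train: bool = False):
        B, C, H, W = x.shape
        mu = x.mean(axis=(2, 3))
        z = self.fc1.forward(mu)
        a = np.maximum(z, 0.0)
        logits = self.fc2.forward(a)
        gate = np.clip(logits + 3.0, 0.0, 6.0) / 6.0
        self._cache = (x, z, logits, gate, (H, W))
        return x * gate[:, :, None, None]

    def backward(self, dout):
        x, z, logits, gate, (H, W) = self._cache
        dgate = (dout * x).sum(axis=(2, 3))
        dlogits = dgate * ((logits > -3) & (logits < 3)) / 6.0
        da = self.fc2.backward(dlogits)
        dmu = self.fc1.backward(da * (z > 0))
        return dout * gate[:, :, None, None] + dmu[:, :, None, None] / (H * W)


class Bneck(nn.Module):
    """Inverted residual block: expand -> depthwise -> (SE) -> linear project."""

    def __init__(self, spec: BneckSpec, config: ModelConfig,
                 rng: np.random.Generator):
        self.spec = spec
        bn = config.use_batchnorm
        self.expand = None
        if spec.expand_channels != spec.in_channels:
            self.expand = nn.Conv2d(spec.in_channels, spec.expand_channels, 1,
                                    bias=not bn, rng=rng)
        self.expand_bn = nn.BatchNorm2d(spec.expand_channels) if bn else None
        self.expand_act = _activation(spec.activation)
        self.dw = nn.DepthwiseConv2d(spec.expand_channels, spec.kernel,
                                     stride=spec.stride, bias=not bn, rng=rng)
        self.dw_bn = nn.BatchNorm2d(spec.expand_channels) if bn else None
        self.dw_act = _activation(spec.activation)
        self.se = (_SEUnit(spec.expand_channels, config.se_reduction, rng)
                   if spec.use_se else None)
        self.project = nn.Conv2d(spec.expand_channels, spec.out_channels, 1,
                                 bias=not bn, rng=rng)
        self.project_bn = nn.BatchNorm2d(spec.out_channels) if bn else None

    def forward(self, x, train: bool = False):
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} channels, got {x.shape[1]}")
        h = x
        if self.expand is not None:
            h = self.expand.forward(h)
        if self.expand_bn is not None:
            h = self.expand_bn.forward(h, train=train)
        h = self.expand_act.forward(h)
        h = self.dw.forward(h)
        if self.dw_bn is not None:
            h = self.dw_bn.forward(h, train=train)
        h = self.dw_act.forward(h)
        if self.se is not None:
            h = self.se.forward(h, train=train)
        h = self.project.forward(h)
        if self.project_bn is not None:
            h = self.project_bn.forward(h, train=train)
        return x + h if self.spec.has_skip else h

    def backward(self, dout):
        dh = dout
        if self.project_bn is not None:
            dh = self.project_bn.backward(dh)
        dh = self.project.backward(dh)
        if self.se is not None:
            dh = self.se.backward(dh)
        dh = self.dw_act.backward(dh)
        if self.dw_bn is not None:
            dh = self.dw_bn.backward(dh)
        dh = self.dw.backward(dh)
        dh = self.expand_act.backward(dh)
        if self.expand_bn is not None:
            dh = self.expand_bn.backward(dh)
        if self.expand is not None:
            dh = self.expand.backward(dh)
        return dout + dh if self.spec.has_skip else dh


def _scale_spec(spec: BneckSpec, width: float) -> BneckSpec:
    return replace(
        spec,
        in_channels=make_divisible(spec.in_channels * width),
        expand_channels=make_divisible(spec.expand_channels * width),
        out_channels=make_divisible(spec.out_channels * width),
    )


class MobileNetV3(nn.Module):
    """stem -> bneck stack -> 1×1 conv -> GAP -> dropout -> linear head."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        bn = cfg.use_batchnorm
        w = cfg.width_multiplier
        stem_ch = make_divisible(cfg.stem_channels * w)
        self.scaled_specs = []
        prev = stem_ch
        for spec in cfg.bneck_specs:
            s = _scale_spec(spec, w)
            s = replace(s, in_channels=prev)
            self.scaled_specs.append(s)
            prev = s.out_channels
        last_ch = make_divisible(cfg.last_channels * w)

        self.stem = nn.Conv2d(cfg.input_channels, stem_ch, 3, stride=2,
                              bias=not bn, rng=rng)
        self.stem_bn = nn.BatchNorm2d(stem_ch) if bn else None
        self.stem_act = nn.HSwish()
        self.blocks = [Bneck(s, cfg, rng) for s in self.scaled_specs]
        self.last_conv = nn.Conv2d(prev, last_ch, 1, bias=not bn, rng=rng)
        self.last_bn = nn.BatchNorm2d(last_ch) if bn else None
        self.last_act = nn.HSwish()
        self.pool = nn.GlobalAvgPool()
        self.dropout = nn.Dropout(cfg.dropout, rng=np.random.default_rng(cfg.seed + 1))
        self.head = nn.Linear(last_ch, cfg.n_classes, rng=rng)

    def forward(self, x, train: bool = False):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None]
        h = self.stem.forward(x)
        if self.stem_bn is not None:
            h = self.stem_bn.forward(h, train=train)
        h = self.stem_act.forward(h)
        for block in self.blocks:
            h = block.forward(h, train=train)
        h = self.last_conv.forward(h)
        if self.last_bn is not None:
            h = self.last_bn.forward(h, train=train)
        h = self.last_act.forward(h)
        h = self.pool.forward(h)
        h = self.dropout.forward(h, train=train)
        return self.head.forward(h)          # logits (B, n_classes)

    def backward(self, dout):
        dh = self.head.backward(dout)
        dh = self.dropout.backward(dh)
        dh = self.pool.backward(dh)
        dh = self.last_act.backward(dh)
        if self.last_bn is not None:
            dh = self.last_bn.backward(dh)
        dh = self.last_conv.backward(dh)
        for block in reversed(self.blocks):
            dh = block.backward(dh)
        dh = self.stem_act.backward(dh)
        if self.stem_bn is not None:
            dh = self.stem_bn.backward(dh)
        return self.stem.backward(dh)


def build_model(config: ModelConfig | None = None) -> MobileNetV3:
    return MobileNetV3(config)


@dataclass
class Hyperparams:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 32
    momentum: float = 0.9
    weight_decay: float = 0.0
    augment: bool = False     # horizontal flip + small shifts during training
    max_shift: int = 3


def _augment_batch(xb: np.ndarray, max_shift: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Label-preserving augmentation: mirror flips and small translations.

    Roll-based shifts wrap around, which is harmless here because slice
    borders are background.
    """
    xb = xb.copy()
    flips = rng.random(len(xb)) < 0.5
    xb[flips] = xb[flips, :, :, ::-1]
    if max_shift > 0:
        shifts = rng.integers(-max_shift, max_shift + 1, size=(len(xb), 2))
        for i, (dy, dx) in enumerate(shifts):
            xb[i] = np.roll(xb[i], (int(dy), int(dx)), axis=(1, 2))
    return xb


def _accuracy(model: MobileNetV3, X: np.ndarray, y: np.ndarray,
              batch_size: int = 64) -> tuple[float, float]:
    losses, correct = [], 0
    for start in range(0, len(X), batch_size):
        xb, yb = X[start:start + batch_size], y[start:start + batch_size]
        logits = model.forward(xb, train=False)
        loss, _ = nn.cross_entropy_loss(logits, yb)
        losses.append(loss * len(xb))
        correct += int(np.sum(logits.argmax(axis=1) == yb))
    return correct / len(X), float(np.sum(losses) / len(X))


def train_classifier(
    model: MobileNetV3,
    X_train: np.ndarray,
    y_train: np.ndarray,
    hyper: Hyperparams | None = None,
    seed: int = 0,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> tuple[MobileNetV3, pd.DataFrame]:
    """Cross-entropy training; per-epoch train/val accuracy and loss history."""
    hyper = hyper or Hyperparams()
    y_train = np.asarray(y_train, dtype=np.int64)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain at least two classes")
    if hyper.optimizer == "adam":
        opt = nn.Adam(model.parameters(), lr=hyper.learning_rate,
                      weight_decay=hyper.weight_decay)
    elif hyper.optimizer == "sgd":
        opt = nn.SGD(model.parameters(), lr=hyper.learning_rate,
                     momentum=hyper.momentum, weight_decay=hyper.weight_decay)
    else:
        raise ValueError(f"unknown optimizer {hyper.optimizer!r}")
    rng = np.random.default_rng(seed)
    X_train = np.asarray(X_train, dtype=np.float64)
    if X_train.ndim == 3:
        X_train = X_train[:, None]
    rows = []
    for epoch in range(hyper.epochs):
        order = rng.permutation(len(X_train))
        for start in range(0, len(X_train), hyper.batch_size):
            idx = order[start:start + hyper.batch_size]
            xb = X_train[idx]
            if hyper.augment:
                xb = _augment_batch(xb, hyper.max_shift, rng)
            logits = model.forward(xb, train=True)
            _, dlogits = nn.cross_entropy_loss(logits, y_train[idx])
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
        train_acc, train_loss = _accuracy(model, X_train, y_train)
        row = {"epoch": epoch + 1, "train_acc": train_acc, "train_loss": train_loss}
        if X_val is not None:
            Xv = np.asarray(X_val, dtype=np.float64)
            if Xv.ndim == 3:
                Xv = Xv[:, None]
            val_acc, val_loss = _accuracy(model, Xv, np.asarray(y_val, dtype=np.int64))
            row.update({"val_acc": val_acc, "val_loss": val_loss})
        rows.append(row)
    return model, pd.DataFrame(rows)


def predict(model: MobileNetV3, images: np.ndarray,
            batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Row-stochastic class probabilities and argmax labels."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    if images.ndim == 3:
        images = images[:, None]
    probs = []
    for start in range(0, len(images), batch_size):
        logits = model.forward(images[start:start + batch_size], train=False)
        probs.append(nn.softmax(logits))
    probs = np.concatenate(probs, axis=0)
    return probs, probs.argmax(axis=1)
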