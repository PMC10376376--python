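"""Pluggable CNN training harness and confusion-matrix metrics.

The harness trains a binary normal/lesion classifier on tooth tiles with
stochastic gradient descent with momentum (SGDM), a step learning-rate
schedule (lr0 * factor^floor((epoch-1)/period)), periodic validation, and
a training log whose columns mirror the usual epoch / iteration /
elapsed-time / mini-batch and validation accuracy / loss layout.

Backbones are registered by name in :data:`BACKBONES`; the default is a
small four-conv-block network written in numpy (im2col convolutions) that
trains on one CPU in minutes.  Heavier architectures can be plugged in by
registering a factory with the same ``(side, n_classes, rng) -> model``
signature.

Metrics use *lesion* as the positive class throughout:
accuracy = diagonal share, precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = harmonic mean of precision and recall.  A metric with a zero
denominator is reported as undefined (None), never as 0.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .dataset import TileDataset, materialize
from .util import fit_to_square

__all__ = [
    "CLASSES",
    "TrainConfig",
    "ConfusionMatrix",
    "MetricsReport",
    "TrainingDiverged",
    "BACKBONES",
    "register_backbone",
    "learning_rate_schedule",
    "build_model",
    "prepare_tiles",
    "train",
    "save_model",
    "load_model",
    "predict",
    "evaluate",
    "metrics_from_confusion",
    "LOG_COLUMNS",
]

CLASSES = ("normal", "lesion")      # lesion = positive class (index 1)

LOG_COLUMNS = ["epoch", "iteration", "time_elapsed", "minibatch_accuracy",
               "validation_accuracy", "minibatch_loss", "validation_loss"]


class TrainingDiverged(RuntimeError):
    """Loss became non-finite; the aborted run's log is attached."""

    def __init__(self, log):
        super().__init__("training diverged: non-finite loss")
        self.log = log


@dataclass
class TrainConfig:
    max_epoch: int = 50
    initial_learning_rate: float = 1e-4
    mini_batch_size: int = 32
    learn_drop_period: int = 5
    learn_rate_drop_factor: float = 0.2
    validation_frequency: int = 3          # in iterations
    optimizer: str = "sgdm"                # "sgdm" or "adam"
    momentum: float = 0.9
    seed: int = 0
    backbone: str = "small_cnn"
    input_side: int = 32

    def validate(self) -> None:
        if min(self.max_epoch, self.mini_batch_size, self.learn_drop_period,
               self.validation_frequency, self.input_side) < 1:
            raise ValueError("integer hyperparameters must be positive")
        if self.initial_learning_rate <= 0:
            raise ValueError("initial_learning_rate must be > 0")
        if not (0 < self.learn_rate_drop_factor <= 1):
            raise ValueError("learn_rate_drop_factor must be in (0, 1]")
        if self.optimizer not in ("sgdm", "adam"):
            raise ValueError("optimizer must be 'sgdm' or 'adam'")
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone '{self.backbone}'")


def learning_rate_schedule(epoch: int, lr0: float = 1e-4,
                           factor: float = 0.2, period: int = 5) -> float:
    """Step schedule: lr0 * factor**floor((epoch - 1) / period), epoch >= 1."""
    return lr0 * factor ** ((epoch - 1) // period)


# ---------------------------------------------------------------------------
# numpy layers

class _Param:
    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.state: dict = {}


class _Conv3x3:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * 9))
        self.w = _Param(rng.normal(0.0, std, size=(cout, cin * 9)))
        self.b = _Param(np.zeros(cout))
        self.params = [self.w, self.b]

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = np.empty((n, c, 3, 3, h, w), dtype=x.dtype)
        for i in range(3):
            for j in range(3):
                cols[:, :, i, j] = xp[:, :, i:i + h, j:j + w]
        return cols.reshape(n, c * 9, h * w)

    @staticmethod
    def _col2im(gcols: np.ndarray, shape) -> np.ndarray:
        n, c, h, w = shape
        g = gcols.reshape(n, c, 3, 3, h, w)
        xp = np.zeros((n, c, h + 2, w + 2), dtype=gcols.dtype)
        for i in range(3):
            for j in range(3):
                xp[:, :, i:i + h, j:j + w] += g[:, :, i, j]
        return xp[:, :, 1:1 + h, 1:1 + w]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        self._cols = self._im2col(x)
        n, c, h, w = x.shape
        y = np.matmul(self.w.value, self._cols)       # (n, cout, h*w)
        return y.reshape(n, -1, h, w) + self.b.value[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, cout, h, w = gy.shape
        g = gy.reshape(n, cout, h * w)
        self.w.grad = np.einsum("nox,nkx->ok", g, self._cols)
        self.b.grad = g.sum(axis=(0, 2))
        gcols = np.matmul(self.w.value.T, g)
        self._cols = None
        return self._col2im(gcols, self._shape)


class _ReLU:
    params: list = []

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class _MaxPool2:
    params: list = []

    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, gy):
        n, c, h, w = self._shape
        g = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(g, self._idx[..., None], gy[..., None], axis=-1)
        g = g.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return g.reshape(n, c, h, w)


class _Flatten:
    params: list = []

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class _Linear:
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / din)
        self.w = _Param(rng.normal(0.0, std, size=(dout, din)))
        self.b = _Param(np.zeros(dout))
        self.params = [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, gy):
        self.w.grad = gy.T @ self._x
        self.b.grad = gy.sum(axis=0)
        gx = gy @ self.w.value
        self._x = None
        return gx


class Sequential:
    def __init__(self, layers, input_side: int):
        self.layers = layers
        self.input_side = input_side

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)

    def parameters(self) -> list[_Param]:
        return [p for layer in self.layers for p in layer.params]


# ---------------------------------------------------------------------------
# backbone registry

BACKBONES: dict = {}


def register_backbone(name: str):
    def deco(fn):
        BACKBONES[name] = fn
        return fn
    return deco


class SkipCNN:
    """Two conv3x3-ReLU-maxpool blocks (8 and 16 channels) whose flattened
    features are concatenated with the raw zero-centered input before the
    linear head (a wide-and-deep input shortcut).

    The shortcut keeps the head's gradient large and input-conditioned
    from the first iteration, so the net converges dependably under the
    small prescribed learning rate even when trained from scratch on a
    few hundred tiles; the convolutional path then refines the decision.
    """

    def __init__(self, side: int, n_classes: int, rng: np.random.Generator):
        if side % 4 != 0:
            raise ValueError("small_cnn needs input_side divisible by 4")
        self.input_side = side
        self.blocks = []
        cin = 1
        for cout in (8, 16):
            self.blocks += [_Conv3x3(cin, cout, rng), _ReLU(), _MaxPool2()]
            cin = cout
        feat = (side // 4) ** 2 * cin + side * side
        self.head = _Linear(feat, n_classes, rng)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n = x.shape[0]
        self._xflat = x.reshape(n, -1)
        h = x
        for layer in self.blocks:
            h = layer.forward(h, train)
        self._hshape = h.shape
        z = np.concatenate([h.reshape(n, -1), self._xflat], axis=1)
        return self.head.forward(z, train)

    def backward(self, gy: np.ndarray) -> None:
        gz = self.head.backward(gy)
        nh = int(np.prod(self._hshape[1:]))
        gh = gz[:, :nh].reshape(self._hshape)
        for layer in reversed(self.blocks):
            gh = layer.backward(gh)

    def parameters(self) -> list[_Param]:
        return ([p for layer in self.blocks for p in layer.params]
                + self.head.params)


@register_backbone("small_cnn")
def _small_cnn(side: int, n_classes: int, rng: np.random.Generator) -> SkipCNN:
    return SkipCNN(side, n_classes, rng)


@register_backbone("cnn4")
def _cnn4(side: int, n_classes: int, rng: np.random.Generator) -> Sequential:
    """Four conv3x3-ReLU-maxpool blocks (8, 16, 32, 32 channels), flatten,
    linear head.  Requires the input side to be divisible by 16."""
    if side % 16 != 0:
        raise ValueError("cnn4 needs input_side divisible by 16")
    layers = []
    cin = 1
    for cout in (8, 16, 32, 32):
        layers += [_Conv3x3(cin, cout, rng), _ReLU(), _MaxPool2()]
        cin = cout
    feat = (side // 16) ** 2 * cin
    layers += [_Flatten(), _Linear(feat, n_classes, rng)]
    return Sequential(layers, side)


@register_backbone("linear")
def _linear_model(side: int, n_classes: int, rng: np.random.Generator) -> Sequential:
    """Multinomial logistic regression on raw pixels (sanity baseline)."""
    return Sequential([_Flatten(), _Linear(side * side, n_classes, rng)], side)


def build_model(config: TrainConfig) -> Sequential:
    config.validate()
    rng = np.random.default_rng(config.seed)
    return BACKBONES[config.backbone](config.input_side, len(CLASSES), rng)


# ---------------------------------------------------------------------------
# training

def prepare_tiles(tiles, side: int) -> tuple[np.ndarray, np.ndarray]:
    """Tiles -> (X, y): X is (N, 1, side, side) float64, zero-centered
    (gray - 127.5) but NOT rescaled — the convention of mainstream
    deep-learning toolboxes' image input layers, and the scale the default
    learning rate is calibrated to; y holds class indices per
    :data:`CLASSES`."""
    xs = np.stack([fit_to_square(t.pixels.astype(np.float64), side)
                   for t in tiles])
    x = xs[:, None, :, :] - 127.5
    y = np.array([CLASSES.index(t.label) for t in tiles], dtype=np.int64)
    return x, y


def _softmax_xent(logits: np.ndarray, y: np.ndarray):
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = len(y)
    loss = -logp[np.arange(n), y].mean()
    p = np.exp(logp)
    p[np.arange(n), y] -= 1.0
    return float(loss), p / n


def _sgdm_step(params, lr: float, momentum: float) -> None:
    for p in params:
        v = p.state.setdefault("v", np.zeros_like(p.value))
        v *= momentum
        v -= lr * p.grad
        p.value += v


def _adam_step(params, lr: float, t: int, b1=0.9, b2=0.999, eps=1e-8) -> None:
    for p in params:
        m = p.state.setdefault("m", np.zeros_like(p.value))
        v = p.state.setdefault("v2", np.zeros_like(p.value))
        m += (1 - b1) * (p.grad - m)
        v += (1 - b2) * (p.grad ** 2 - v)
        mh = m / (1 - b1 ** t)
        vh = v / (1 - b2 ** t)
        p.value -= lr * mh / (np.sqrt(vh) + eps)


def _eval_loss_acc(model, X, y, batch: int = 64):
    losses, correct = [], 0
    for i in range(0, len(y), batch):
        logits = model.forward(X[i:i + batch], train=False)
        loss, _ = _softmax_xent(logits, y[i:i + batch])
        losses.append(loss * len(y[i:i + batch]))
        correct += int((logits.argmax(axis=1) == y[i:i + batch]).sum())
    return sum(losses) / len(y), correct / len(y)


def train(dataset: TileDataset, config: TrainConfig | None = None):
    """Train the configured backbone on an augmented tile dataset.

    Returns ``(model, log)`` where ``log`` is a pandas DataFrame with
    one row per iteration (validation columns filled every
    ``validation_frequency`` iterations and on the first and last one).
    Raises :class:`TrainingDiverged` when the loss becomes non-finite.
    """
    import pandas as pd

    config = config or TrainConfig()
    config.validate()
    splits = materialize(dataset, augment_train=True, augment_val=False)
    for which in ("train", "val"):
        tiles = splits[which]
        if len(tiles) == 0:
            raise ValueError(f"empty {which} split")
        if len({t.label for t in tiles}) < 2:
            raise ValueError(f"single-class {which} split")
    Xtr, ytr = prepare_tiles(splits["train"], config.input_side)
    Xva, yva = prepare_tiles(splits["val"], config.input_side)

    model = build_model(config)
    params = model.parameters()
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    t0 = time.monotonic()
    iteration = 0
    iters_per_epoch = max(1, len(ytr) // config.mini_batch_size)
    total_iters = config.max_epoch * iters_per_epoch
    for epoch in range(1, config.max_epoch + 1):
        lr = learning_rate_schedule(epoch, config.initial_learning_rate,
                                    config.learn_rate_drop_factor,
                                    config.learn_drop_period)
        order = rng.permutation(len(ytr))
        for k in range(iters_per_epoch):
            iteration += 1
            idx = order[k * config.mini_batch_size:
                        (k + 1) * config.mini_batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            logits = model.forward(xb, train=True)
            loss, gy = _softmax_xent(logits, yb)
            acc = float((logits.argmax(axis=1) == yb).mean())
            row = {"epoch": epoch, "iteration": iteration,
                   "time_elapsed": time.monotonic() - t0,
                   "minibatch_accuracy": acc,
                   "validation_accuracy": np.nan,
                   "minibatch_loss": loss, "validation_loss": np.nan}
            if not np.isfinite(loss):
                row["diverged"] = True
                rows.append(row)
                raise TrainingDiverged(pd.DataFrame(rows))
            model.backward(gy)
            if config.optimizer == "sgdm":
                _sgdm_step(params, lr, config.momentum)
            else:
                _adam_step(params, lr, iteration)
            if (iteration == 1 or iteration == total_iters
                    or iteration % config.validation_frequency == 0):
                vloss, vacc = _eval_loss_acc(model, Xva, yva)
                row["validation_accuracy"] = vacc
                row["validation_loss"] = vloss
            rows.append(row)
    log = pd.DataFrame(rows, columns=LOG_COLUMNS)
    return model, log


def save_model(model: Sequential, config: TrainConfig, path) -> None:
    """Persist parameter arrays plus the backbone identity as an npz."""
    import json

    meta = {"backbone": config.backbone, "input_side": config.input_side,
            "seed": config.seed}
    arrays = {f"p{i}": p.value for i, p in enumerate(model.parameters())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> Sequential:
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cfg = TrainConfig(backbone=meta["backbone"],
                          input_side=meta["input_side"], seed=meta["seed"])
        model = build_model(cfg)
        for i, p in enumerate(model.parameters()):
            p.value[...] = data[f"p{i}"]
    return model


def predict(model: Sequential, tiles) -> np.ndarray:
    """Hard argmax class index per tile."""
    X, _y = prepare_tiles(tiles, model.input_side)
    out = []
    for i in range(0, len(X), 64):
        out.append(model.forward(X[i:i + 64], train=False).argmax(axis=1))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# confusion matrix and metrics

@dataclass
class ConfusionMatrix:
    """2x2 tally, rows = predicted, columns = actual, order per CLASSES."""
    cells: np.ndarray
    classes: tuple[str, str] = CLASSES

    def validate(self) -> None:
        c = np.asarray(self.cells, dtype=np.float64)
        if c.shape != (2, 2) or (c < 0).any():
            raise ValueError("cells must be a 2x2 non-negative array")

    @property
    def total(self) -> float:
        return float(np.asarray(self.cells).sum())


def evaluate(model: Sequential, tiles) -> ConfusionMatrix:
    """Tally hard predictions on ``tiles`` into a confusion matrix."""
    if len(tiles) == 0:
        raise ValueError("empty evaluation split")
    yhat = predict(model, tiles)
    y = np.array([CLASSES.index(t.label) for t in tiles])
    cells = np.zeros((2, 2), dtype=np.int64)
    for p, a in zip(yhat, y):
        cells[p, a] += 1
    return ConfusionMatrix(cells=cells)


@dataclass
class MetricsReport:
    """Percentages; a metric whose denominator is zero is None."""
    accuracy: float | None
    recall: float | None
    precision: float | None
    f1: float | None

    def rounded(self) -> dict:
        return {k: (None if v is None else round(v, 1))
                for k, v in self.__dict__.items()}


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    cm.validate()
    c = np.asarray(cm.cells, dtype=np.float64)
    tp, fp = c[1, 1], c[1, 0]
    fn, tn = c[0, 1], c[0, 0]

    def ratio(num, den):
        return None if den == 0 else 100.0 * num / den

    accuracy = ratio(tp + tn, c.sum())
    recall = ratio(tp, tp + fn)
    precision = ratio(tp, tp + fp)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(accuracy=accuracy, recall=recall,
                         precision=precision, f1=f1)
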