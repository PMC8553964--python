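"""Three-block convolutional network for 96 x 96 grayscale inputs.

The architecture follows the classical small-image pattern used for
time-frequency HFO images: three convolution + batch-normalization +
ReLU + 2x2 max-pooling blocks, a fully connected layer with dropout,
and a two-way softmax (class 0 = epileptogenic, 1 = non-epileptogenic).
Layers, forward/backward passes and SGD-with-momentum are implemented
directly on NumPy arrays (im2col convolutions in float32), which keeps
training deterministic per seed on a single CPU.

Dataset handling mirrors the evaluation protocol: stratified 70/15/15
train/validation/test splits, model selection on validation accuracy,
and repeated randomized rounds that re-split and retrain from scratch.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import TrainingDivergedError
from .metrics import ConfusionCounts, ScoreTriple, confusion, scores

__all__ = [
    "ArchConfig",
    "TrainConfig",
    "TrainResult",
    "RoundsResult",
    "CnnClassifier",
    "build_model",
    "split_dataset",
    "train",
    "predict",
    "run_rounds",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArchConfig:
    """Network hyperparameters.

    Exactly three conv + pool blocks are required; kernel size, filter
    counts, the fully connected width and the dropout rate are free.
    """

    kernel_size: int = 3
    filters: tuple[int, int, int] = (8, 16, 32)
    batch_norm: bool = True
    fc_width: int = 128
    dropout_rate: float = 0.5
    input_size: int = 96

    def __post_init__(self):
        if len(self.filters) != 3:
            raise ValueError("exactly three convolution blocks are required")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    ``lr`` is the *initial* learning rate (default 0.01); it is halved
    every ``lr_step`` epochs, which tames the gradient noise of plain
    SGD on small image cohorts.
    """

    lr: float = 0.01
    momentum: float = 0.9
    epochs: int = 15
    batch_size: int = 32
    lr_step: int = 5
    seed: int = 0
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


# ---------------------------------------------------------------------------
# layers


class _Conv:
    def __init__(self, rng, c_in, c_out, k):
        fan_in = c_in * k * k
        self.w = (rng.standard_normal((c_out, c_in, k, k))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k

    def forward(self, x, train):
        b, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k),
                                                       axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * self.k**2)
        self._cols = cols
        self._shape = (b, c, h, w)
        wm = self.w.reshape(self.w.shape[0], -1)
        out = cols @ wm.T + self.b
        return out.reshape(b, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        b, c, h, w = self._shape
        k, p = self.k, self.k // 2
        f = self.w.shape[0]
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, f)
        wm = self.w.reshape(f, -1)
        self.dw = (dmat.T @ self._cols).reshape(self.w.shape)
        self.db = dmat.sum(axis=0)
        dcols = (dmat @ wm).reshape(b, h, w, c, k, k)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w]

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class _BatchNorm:
    eps = 1e-5

    def __init__(self, channels, momentum=0.9):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum

    def forward(self, x, train):
        axes = (0, 2, 3)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mu).astype(np.float32)
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var).astype(np.float32)
        else:
            mu, var = self.run_mean, self.run_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * ivstd[None, :, None, None]
        if train:
            self._cache = (xhat, ivstd, x.shape[0] * x.shape[2] * x.shape[3])
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        xhat, ivstd, n = self._cache
        axes = (0, 2, 3)
        self.dgamma = (dout * xhat).sum(axis=axes)
        self.dbeta = dout.sum(axis=axes)
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (ivstd[None, :, None, None] / n) * (
            n * dxhat
            - dxhat.sum(axis=axes)[None, :, None, None]
            - xhat * (dxhat * xhat).sum(axis=axes)[None, :, None, None]
        )
        self._cache = None
        return dx.astype(np.float32)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}


class _ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        d = dout * self._mask
        self._mask = None
        return d

    def params(self):
        return {}

    def grads(self):
        return {}


class _MaxPool2:
    def forward(self, x, train):
        b, c, h, w = x.shape
        r = x.reshape(b, c, h // 2, 2, w // 2, 2)
        out = r.max(axis=(3, 5))
        up = np.repeat(np.repeat(out, 2, axis=2), 2, axis=3)
        mask = (x == up)
        counts = mask.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
        self._cache = (mask, counts)
        return out

    def backward(self, dout):
        mask, counts = self._cache
        spread = dout / counts
        up = np.repeat(np.repeat(spread, 2, axis=2), 2, axis=3)
        self._cache = None
        return (up * mask).astype(np.float32)

    def params(self):
        return {}

    def grads(self):
        return {}


class _Flatten:
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def params(self):
        return {}

    def grads(self):
        return {}


class _Dense:
    def __init__(self, rng, n_in, n_out):
        self.w = (rng.standard_normal((n_out, n_in))
                  * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, train):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dout):
        self.dw = dout.T @ self._x
        self.db = dout.sum(axis=0)
        dx = dout @ self.w
        self._x = None
        return dx

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class _Dropout:
    def __init__(self, rate):
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        d = dout * self._mask
        self._mask = None
        return d

    def params(self):
        return {}

    def grads(self):
        return {}


# ---------------------------------------------------------------------------
# model


class CnnClassifier:
    """Three-block CNN with a two-way softmax head."""

    def __init__(self, arch: ArchConfig, seed: int = 0):
        self.arch = arch
        rng = np.random.default_rng(seed)
        layers = []
        c_in = 1
        size = arch.input_size
        for c_out in arch.filters:
            layers.append(_Conv(rng, c_in, c_out, arch.kernel_size))
            if arch.batch_norm:
                layers.append(_BatchNorm(c_out))
            layers.append(_ReLU())
            layers.append(_MaxPool2())
            c_in = c_out
            size //= 2
        layers.append(_Flatten())
        layers.append(_Dense(rng, c_in * size * size, arch.fc_width))
        layers.append(_ReLU())
        self._dropout = _Dropout(arch.dropout_rate)
        layers.append(self._dropout)
        layers.append(_Dense(rng, arch.fc_width, 2))
        self.layers = layers

    def reseed_dropout(self, seed: int) -> None:
        self._dropout.rng = np.random.default_rng(seed)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for lay in self.layers for p in lay.params().values()))

    #: fixed input centering: images live in [0, 1], the network sees x - 0.5
    input_offset = 0.5

    def forward(self, x, train=False):
        out = np.asarray(x, dtype=np.float32)
        if out.ndim == 3:
            out = out[:, None, :, :]
        out = out - self.input_offset
        for lay in self.layers:
            out = lay.forward(out, train)
        return out

    def predict_proba(self, x, batch_size: int = 256):
        probs = []
        x = np.asarray(x, dtype=np.float32)
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            probs.append(_softmax(logits))
        return np.concatenate(probs, axis=0)

    def get_state(self):
        return copy.deepcopy([lay.params() for lay in self.layers]), copy.deepcopy(
            [(lay.run_mean.copy(), lay.run_var.copy())
             if isinstance(lay, _BatchNorm) else None for lay in self.layers]
        )

    def set_state(self, state):
        params, bn_stats = state
        for lay, saved, stats in zip(self.layers, params, bn_stats):
            for name, value in saved.items():
                getattr(lay, name)[...] = value
            if stats is not None:
                lay.run_mean[...] = stats[0]
                lay.run_var[...] = stats[1]


def _softmax(logits):
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def build_model(arch: ArchConfig, seed: int = 0) -> CnnClassifier:
    """Instantiate the network with He-initialized weights."""
    return CnnClassifier(arch, seed=seed)


def split_dataset(labels, split=(0.70, 0.15, 0.15), seed: int = 0):
    """Stratified random train/validation/test partition.

    Returns three disjoint index arrays whose union covers the dataset.
    Within each class the train and validation sizes are floors of the
    requested fractions; the remainder goes to the test set.
    """
    labels = np.asarray(labels)
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    parts = ([], [], [])
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 3:
            raise ValueError(f"class {cls} too small to stratify")
        idx = rng.permutation(idx)
        n_tr = int(np.floor(split[0] * len(idx)))
        n_val = int(np.floor(split[1] * len(idx)))
        parts[0].append(idx[:n_tr])
        parts[1].append(idx[n_tr : n_tr + n_val])
        parts[2].append(idx[n_tr + n_val :])
    return tuple(np.sort(np.concatenate(p)) for p in parts)


@dataclass
class TrainResult:
    curves: pd.DataFrame  # epoch, train_loss, train_acc, val_acc
    best_epoch: int
    best_val_acc: float


def _accuracy(model, x, y):
    preds = predict(model, x)
    return float(np.mean(preds == y))


def train(model: CnnClassifier, x_train, y_train, x_val, y_val,
          config: TrainConfig) -> TrainResult:
    """SGD-with-momentum training with validation-based model selection.

    The model is left holding the parameter state of the epoch with the
    highest validation accuracy.  A non-finite loss raises
    :class:`TrainingDivergedError` naming the epoch.
    """
    x_train = np.asarray(x_train, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=int)
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("training and validation sets must be nonempty")
    rng = np.random.default_rng(config.seed)
    model.reseed_dropout(config.seed + 1)
    velocity = [{k: np.zeros_like(v) for k, v in lay.params().items()}
                for lay in model.layers]
    best = (-1.0, 0, model.get_state())
    rows = []
    for epoch in range(1, config.epochs + 1):
        lr = config.lr * 0.5 ** ((epoch - 1) // config.lr_step)
        order = rng.permutation(len(x_train))
        losses = []
        correct = 0
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            xb = x_train[sel]
            if xb.ndim == 3:
                xb = xb[:, None]
            yb = y_train[sel]
            out = xb - model.input_offset
            for lay in model.layers:
                out = lay.forward(out, True)
            probs = _softmax(out)
            loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            losses.append(loss)
            correct += int(np.sum(np.argmax(probs, axis=1) == yb))
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            grad = (grad / len(yb)).astype(np.float32)
            for lay in reversed(model.layers):
                grad = lay.backward(grad)
            for lay, vel in zip(model.layers, velocity):
                grads = lay.grads()
                for name, g in grads.items():
                    v = vel[name]
                    v *= config.momentum
                    v -= lr * g
                    lay.params()[name][...] += v
        val_acc = _accuracy(model, x_val, y_val)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "train_acc": correct / len(x_train), "val_acc": val_acc})
        if val_acc > best[0]:
            best = (val_acc, epoch, model.get_state())
    model.set_state(best[2])
    return TrainResult(pd.DataFrame(rows), best_epoch=best[1], best_val_acc=best[0])


def predict(model: CnnClassifier, images) -> np.ndarray:
    """Hard labels by softmax argmax; a tie breaks toward class 0 (EZ)."""
    probs = model.predict_proba(images)
    return np.argmax(probs, axis=1)


@dataclass
class RoundsResult:
    """Per-round confusion counts and scores from repeated evaluation."""

    rounds: list[dict] = field(default_factory=list)
    failed_rounds: list[int] = field(default_factory=list)

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    def score_triples(self) -> list[ScoreTriple]:
        return [r["scores"] for r in self.rounds]

    def accuracies(self) -> np.ndarray:
        return np.array([r["scores"].accuracy for r in self.rounds])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rounds:
            cc: ConfusionCounts = r["confusion"]
            st: ScoreTriple = r["scores"]
            rows.append({"round": r["round"], "TP": cc.tp, "FN": cc.fn,
                         "FP": cc.fp, "TN": cc.tn,
                         "sensitivity": st.sensitivity,
                         "specificity": st.specificity,
                         "accuracy": st.accuracy})
        return pd.DataFrame(rows)


def run_rounds(images, labels, arch: ArchConfig, config: TrainConfig,
               n_rounds: int = 100) -> RoundsResult:
    """Repeat split / train / test ``n_rounds`` times.

    Round ``r`` uses seed ``config.seed + r`` for its split, weight
    initialization and batch shuffling, so rounds are independent and
    the whole evaluation is reproducible.  A diverged round is logged,
    excluded and reported in ``failed_rounds``.
    """
    if n_rounds < 1:
        raise ValueError("need at least one round")
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels, dtype=int)
    result = RoundsResult()
    for rnd in range(n_rounds):
        seed = config.seed + rnd
        tr, val, te = split_dataset(labels, config.split, seed=seed)
        assert not (set(te) & (set(tr) | set(val))), "test-set leakage"
        model = build_model(arch, seed=seed)
        round_cfg = dataclasses.replace(config, seed=seed)
        try:
            fit = train(model, images[tr], labels[tr], images[val], labels[val],
                        round_cfg)
        except TrainingDivergedError as exc:
            logger.warning("round %d aborted: %s", rnd, exc)
            result.failed_rounds.append(rnd)
            continue
        preds = predict(model, images[te])
        cc = confusion(labels[te], preds)
        result.rounds.append({"round": rnd, "seed": seed, "confusion": cc,
                              "scores": scores(cc), "curves": fit.curves,
                              "best_epoch": fit.best_epoch})
    return result
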