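"""Reference host classifiers, optimisers and the training loop.

Networks are implemented directly on numpy (float64) with analytic
gradients; correctness is pinned by finite-difference tests.  Every model
exposes

* ``params``      — dict of named parameter arrays (updated in place),
* ``forward``     — returns ``(probs, cache)``,
* ``loss_grad``   — mean-reduced cross-entropy and its gradient at the logits,
* ``backward``    — returns ``(param_grads, dinput)``.

``dinput`` is the loss gradient at the model input, which is what the gate
layer's gradient collection consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import TimeSeriesDataset
from .exceptions import DimensionError
from . import extension as ext_mod

__all__ = [
    "TrainingConfig",
    "ShallowSoftmax",
    "LSTMPerStep",
    "shallow_softmax_classifier",
    "lstm_per_step_classifier",
    "make_optimizer",
    "Adam",
    "RMSprop",
    "fit",
    "fit_repeated",
    "FitResult",
    "EEGNET_REFERENCE_CONFIG",
]

# Hyperparameters of the compact convolutional EEG architecture referenced as
# an optional host model; recorded for configuration completeness, not
# exercised here (requires external EEG recordings).
EEGNET_REFERENCE_CONFIG = {
    "electrodes": 32,
    "chunk_size": 188,
    "K1": 32,
    "K2": 32,
    "F1": 8,
    "F2": 16,
    "D": 2,
    "dropout": 0.5,
    "lstm_hidden": 188,
}


@dataclass
class TrainingConfig:
    optimiser: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 32
    split: float = 0.7
    seed: int = 0
    runs: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.split < 1.0:
            raise ValueError(f"split must be in (0, 1); got {self.split}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1; got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1; got {self.batch_size}")

    def with_seed(self, seed: int) -> "TrainingConfig":
        return TrainingConfig(
            optimiser=self.optimiser,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            split=self.split,
            seed=seed,
            runs=self.runs,
        )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _one_hot(y: np.ndarray, k: int) -> np.ndarray:
    return np.eye(k)[y]


class ShallowSoftmax:
    """Flatten the window and map linearly to class probabilities."""

    def __init__(self, input_steps: int, channels: int, classes: int, rng):
        if min(input_steps, channels, classes) < 1:
            raise DimensionError("all dimensions must be positive")
        d = input_steps * channels
        self.input_steps = input_steps
        self.channels = channels
        self.classes = classes
        self.per_step = False
        self.params = {
            "W": rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, classes)),
            "b": np.zeros(classes),
        }

    def forward(self, x: np.ndarray, rng=None, train: bool = False):
        flat = x.reshape(x.shape[0], -1)
        logits = flat @ self.params["W"] + self.params["b"]
        return _softmax(logits), {"flat": flat, "shape": x.shape}

    def loss_grad(self, probs: np.ndarray, y: np.ndarray):
        n = probs.shape[0]
        p = probs[np.arange(n), y]
        with np.errstate(divide="ignore"):
            loss = float(-np.log(p).mean())
        dlogits = (probs - _one_hot(y, self.classes)) / n
        return loss, dlogits

    def backward(self, cache, dlogits):
        flat = cache["flat"]
        grads = {
            "W": flat.T @ dlogits,
            "b": dlogits.sum(axis=0),
        }
        dx = (dlogits @ self.params["W"].T).reshape(cache["shape"])
        return grads, dx


class LSTMPerStep:
    """Single LSTM layer emitting a class-probability vector per time step.

    Hidden sequence passes through dropout before a shared linear+softmax
    output layer, so a window of ``t'`` steps yields a ``t' x classes``
    probability matrix per instance.
    """

    def __init__(self, hidden_units: int, channels: int, classes: int, dropout: float, rng):
        if hidden_units < 1:
            raise DimensionError("hidden_units must be >= 1")
        if not 0.0 <= dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1); got {dropout}")
        self.hidden = hidden_units
        self.channels = channels
        self.classes = classes
        self.dropout = dropout
        self.per_step = True
        h, c = hidden_units, channels
        sx, sh = 1.0 / np.sqrt(c), 1.0 / np.sqrt(h)
        self.params = {
            "Wx": rng.normal(0.0, sx, size=(c, 4 * h)),
            "Wh": rng.normal(0.0, sh, size=(h, 4 * h)),
            "bg": np.zeros(4 * h),
            "Wy": rng.normal(0.0, sh, size=(h, classes)),
            "by": np.zeros(classes),
        }

    def forward(self, x: np.ndarray, rng=None, train: bool = False):
        n, t, _ = x.shape
        h = self.hidden
        Wx, Wh, bg = self.params["Wx"], self.params["Wh"], self.params["bg"]
        hs = np.zeros((n, t, h))
        cs = np.zeros((n, t, h))
        gates = np.zeros((n, t, 4 * h))
        h_prev = np.zeros((n, h))
        c_prev = np.zeros((n, h))
        for s in range(t):
            a = x[:, s] @ Wx + h_prev @ Wh + bg
            i = _sigmoid(a[:, :h])
            f = _sigmoid(a[:, h : 2 * h])
            g = np.tanh(a[:, 2 * h : 3 * h])
            o = _sigmoid(a[:, 3 * h :])
            c_prev = f * c_prev + i * g
            h_prev = o * np.tanh(c_prev)
            gates[:, s] = np.concatenate([i, f, g, o], axis=1)
            cs[:, s] = c_prev
            hs[:, s] = h_prev
        if train and self.dropout > 0.0:
            if rng is None:
                raise ValueError("training forward with dropout requires an rng")
            mask = (rng.random(hs.shape) >= self.dropout) / (1.0 - self.dropout)
        else:
            mask = np.ones_like(hs)
        hdrop = hs * mask
        logits = hdrop @ self.params["Wy"] + self.params["by"]
        cache = {"x": x, "hs": hs, "cs": cs, "gates": gates, "mask": mask, "hdrop": hdrop}
        return _softmax(logits), cache

    def loss_grad(self, probs: np.ndarray, y: np.ndarray):
        n, t, _ = probs.shape
        p = probs[np.arange(n)[:, None], np.arange(t)[None, :], y]
        with np.errstate(divide="ignore"):
            loss = float(-np.log(p).mean())
        dlogits = (probs - _one_hot(y, self.classes)) / (n * t)
        return loss, dlogits

    def backward(self, cache, dlogits):
        x, hs, cs, gates, mask = (
            cache["x"],
            cache["hs"],
            cache["cs"],
            cache["gates"],
            cache["mask"],
        )
        n, t, _ = x.shape
        h = self.hidden
        Wx, Wh, Wy = self.params["Wx"], self.params["Wh"], self.params["Wy"]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["Wy"] = np.einsum("nth,ntk->hk", cache["hdrop"], dlogits)
        grads["by"] = dlogits.sum(axis=(0, 1))
        dh_seq = (dlogits @ Wy.T) * mask
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, h))
        dc_next = np.zeros((n, h))
        for s in range(t - 1, -1, -1):
            i = gates[:, s, :h]
            f = gates[:, s, h : 2 * h]
            g = gates[:, s, 2 * h : 3 * h]
            o = gates[:, s, 3 * h :]
            c = cs[:, s]
            c_prev = cs[:, s - 1] if s > 0 else np.zeros((n, h))
            h_prev = hs[:, s - 1] if s > 0 else np.zeros((n, h))
            tanh_c = np.tanh(c)
            dh = dh_seq[:, s] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            grads["Wx"] += x[:, s].T @ da
            grads["Wh"] += h_prev.T @ da
            grads["bg"] += da.sum(axis=0)
            dx[:, s] = da @ Wx.T
            dh_next = da @ Wh.T
        return grads, dx


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def shallow_softmax_classifier(input_steps: int, channels: int, classes: int):
    """Constructor for the flatten-linear-softmax reference model."""
    if min(input_steps, channels, classes) < 1:
        raise DimensionError("all dimensions must be positive")

    def factory(rng) -> ShallowSoftmax:
        return ShallowSoftmax(input_steps, channels, classes, rng)

    return factory


def lstm_per_step_classifier(
    hidden_units: int, channels: int, classes: int, dropout: float = 0.2
):
    """Constructor for the per-time-step LSTM reference model."""
    if hidden_units < 1:
        raise DimensionError("hidden_units must be >= 1")

    def factory(rng) -> LSTMPerStep:
        return LSTMPerStep(hidden_units, channels, classes, dropout, rng)

    return factory


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for name, p in params.items():
            g = grads[name]
            m = self.m.setdefault(name, np.zeros_like(p))
            v = self.v.setdefault(name, np.zeros_like(p))
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            mhat = m / (1.0 - self.beta1**self.t)
            vhat = v / (1.0 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop:
    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-8):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict, grads: dict) -> None:
        for name, p in params.items():
            g = grads[name]
            v = self.v.setdefault(name, np.zeros_like(p))
            v += (1.0 - self.rho) * (g * g - v)
            p -= self.lr * g / (np.sqrt(v) + self.eps)


def make_optimizer(name: str, lr: float):
    name = name.lower()
    if name == "adam":
        return Adam(lr)
    if name == "rmsprop":
        return RMSprop(lr)
    raise ValueError(f"unknown optimiser {name!r}; expected 'adam' or 'rmsprop'")


@dataclass
class FitResult:
    model: object
    extension: ext_mod.PairwiseExtension | None
    archive: ext_mod.GradientArchive | None
    train_loss: list[float]
    val_loss: list[float]
    f1_weighted: float
    f1_per_class: np.ndarray
    seed: int
    train_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    val_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def predict(model, dataset: TimeSeriesDataset, index: np.ndarray | None = None):
    """Hard class predictions (per instance or per step) for a dataset slice."""
    x = dataset.data if index is None else dataset.data[index]
    probs, _ = model.forward(x, rng=None, train=False)
    return probs.argmax(axis=-1)


def fit(
    model_factory,
    dataset: TimeSeriesDataset,
    config: TrainingConfig,
    ext: ext_mod.PairwiseExtension | None = None,
) -> FitResult:
    """One seeded training run; returns losses and final validation F1.

    When ``ext`` is None an immutable identity gate is attached internally —
    multiplication by exactly 1.0 — so the training trajectory is bit-identical
    to extension-free training under the same seed and batch order.
    """
    from .stats import f1_scores

    internal = ext is None
    if internal:
        ext = ext_mod.make_extension(
            dataset.time_steps, dataset.channels, ext_mod.MODE_CHANNEL, trainable=False
        )
    run = ext_mod.train_with_extension(model_factory, ext, dataset, config)
    y_val = dataset.labels[run.val_index]
    preds = predict(run.model, dataset, run.val_index)
    if dataset.per_step_labels:
        preds, y_val = preds.ravel(), y_val.ravel()
    f1w, f1c = f1_scores(preds, y_val, dataset.class_count)
    return FitResult(
        model=run.model,
        extension=None if internal else run.extension,
        archive=None if internal else run.archive,
        train_loss=run.train_loss,
        val_loss=run.val_loss,
        f1_weighted=f1w,
        f1_per_class=f1c,
        seed=config.seed,
        train_index=run.train_index,
        val_index=run.val_index,
    )


def fit_repeated(
    model_factory,
    dataset: TimeSeriesDataset,
    config: TrainingConfig,
    make_ext=None,
) -> list[FitResult]:
    """``config.runs`` runs with distinct split/init seeds ``seed + i``.

    ``make_ext`` is an optional zero-argument callable building a fresh gate
    per run (gates accumulate state, so they must not be shared).
    """
    results = []
    for i in range(config.runs):
        cfg = config.with_seed(config.seed + i)
        ext = make_ext() if make_ext is not None else None
        results.append(fit(model_factory, dataset, cfg, ext=ext))
    return results
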