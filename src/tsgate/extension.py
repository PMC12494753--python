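"""Identity-initialised multiplicative gate layer and gradient collection.

The gate layer sits between the input window and the host network and
multiplies every input entry by a dedicated weight:

* ``channel_vector`` mode: one weight per channel, shared over time steps
  (element-wise multiplication upon the data channels);
* ``time_channel_matrix`` mode: a full ``t' x c`` weight matrix (Hadamard
  product), one weight per (time step, channel) cell.

All weights start at exactly 1.0 so the layer is the identity function at
construction.  In immutable mode the weights are never updated; the gradient
of the loss with respect to each gate weight is still computed for every
batch of every epoch and stored in a :class:`GradientArchive` for downstream
profile analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import TimeSeriesDataset
from .exceptions import DimensionError, DatasetError, TrainingError

__all__ = [
    "MODE_CHANNEL",
    "MODE_MATRIX",
    "PairwiseExtension",
    "GradientArchive",
    "make_extension",
    "apply_extension",
    "pairwise_gradient",
    "train_with_extension",
    "TrainingRun",
    "save_archive",
    "load_archive",
]

MODE_CHANNEL = "channel_vector"
MODE_MATRIX = "time_channel_matrix"
_MODES = (MODE_CHANNEL, MODE_MATRIX)


@dataclass
class PairwiseExtension:
    """Trainable or immutable gate weights with identity initialisation."""

    mode: str
    weights: np.ndarray
    trainable: bool = True
    window_steps: int | None = None

    @property
    def channels(self) -> int:
        return self.weights.shape[-1]

    @property
    def feature_shape(self) -> tuple[int, ...]:
        return self.weights.shape

    def apply(self, x: np.ndarray) -> np.ndarray:
        return apply_extension(self, x)


def make_extension(
    window_steps: int, channels: int, mode: str, trainable: bool = True
) -> PairwiseExtension:
    """Build a gate layer with every weight exactly 1.0.

    ``channel_vector`` mode yields a length-``channels`` weight vector;
    ``time_channel_matrix`` mode a ``window_steps x channels`` matrix.
    """
    if window_steps < 1 or channels < 1:
        raise DimensionError(
            f"window_steps and channels must be >= 1; got {window_steps}, {channels}"
        )
    if mode not in _MODES:
        raise DimensionError(f"mode must be one of {_MODES}; got {mode!r}")
    shape = (channels,) if mode == MODE_CHANNEL else (window_steps, channels)
    return PairwiseExtension(
        mode=mode,
        weights=np.ones(shape, dtype=np.float64),
        trainable=trainable,
        window_steps=window_steps,
    )


def apply_extension(ext: PairwiseExtension, x: np.ndarray) -> np.ndarray:
    """Multiply a ``batch x t' x c`` input by the gate weights."""
    x = np.asarray(x)
    if x.ndim != 3:
        raise DimensionError(f"input must be batch x t' x c; got shape {x.shape}")
    if ext.mode == MODE_CHANNEL:
        if x.shape[2] != ext.weights.shape[0]:
            raise DimensionError(
                f"input has {x.shape[2]} channels, gate has {ext.weights.shape[0]}"
            )
    else:
        if x.shape[1:] != ext.weights.shape:
            raise DimensionError(
                f"input window {x.shape[1:]} incompatible with gate {ext.weights.shape}"
            )
    return x * ext.weights


def pairwise_gradient(
    ext: PairwiseExtension, x: np.ndarray, dz: np.ndarray
) -> np.ndarray:
    """Gradient of the loss w.r.t. the gate weights for one batch.

    ``dz`` is the loss gradient at the gate output ``z = x * w``.  By the
    chain rule the channel-mode gradient is the (batch, time) sum of
    ``x * dz``; matrix mode sums over the batch only.
    """
    if ext.mode == MODE_CHANNEL:
        return np.einsum("isj,isj->j", x, dz)
    return np.einsum("isj,isj->sj", x, dz)


@dataclass
class GradientArchive:
    """Raw per-(epoch, batch) gradients of the gate weights.

    ``entries`` has shape ``(epochs, batches_per_epoch, *feature_shape)``
    where ``feature_shape`` is ``(c,)`` in channel mode and ``(t', c)`` in
    matrix mode.
    """

    entries: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.float64)
        expected_ndim = 3 if self.mode == MODE_CHANNEL else 4
        if self.entries.ndim != expected_ndim:
            raise DimensionError(
                f"{self.mode} archive entries must be {expected_ndim}-d; "
                f"got shape {self.entries.shape}"
            )

    @property
    def epochs(self) -> int:
        return self.entries.shape[0]

    @property
    def batches_per_epoch(self) -> int:
        return self.entries.shape[1]

    @property
    def feature_shape(self) -> tuple[int, ...]:
        return self.entries.shape[2:]


def save_archive(
    archive: GradientArchive, path: str | Path, config: dict | None = None
) -> Path:
    """Serialise an archive to a compressed array file plus a JSON sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        entries=archive.entries,
        epochs=np.asarray(archive.epochs),
        batches_per_epoch=np.asarray(archive.batches_per_epoch),
        mode=np.asarray(archive.mode),
        shape=np.asarray(archive.feature_shape),
    )
    path.with_suffix(".json").write_text(json.dumps(config or {}, indent=2, default=str))
    return path


def load_archive(path: str | Path) -> GradientArchive:
    with np.load(path) as npz:
        return GradientArchive(entries=npz["entries"], mode=str(npz["mode"]))


@dataclass
class TrainingRun:
    """Everything produced by one seeded training run."""

    model: object
    extension: PairwiseExtension
    archive: GradientArchive
    train_index: np.ndarray
    val_index: np.ndarray
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)


def _stratified_split(dataset: TimeSeriesDataset, train_fraction: float, seed: int):
    from sklearn.model_selection import train_test_split

    idx = np.arange(dataset.n_instances)
    strat = dataset.instance_labels()
    train_idx, val_idx = train_test_split(
        idx, train_size=train_fraction, stratify=strat, random_state=seed
    )
    return np.sort(train_idx), np.sort(val_idx)


def train_with_extension(
    model_factory,
    ext: PairwiseExtension,
    dataset: TimeSeriesDataset,
    config,
) -> TrainingRun:
    """Train ``NN(gate(x))`` and collect gate gradients from every batch.

    The classification pipeline is ``f(x) = NN(gate(x))``.  If the gate is
    trainable its weights are updated by the same optimiser as the host
    model; if immutable they stay exactly 1.0 throughout and only the
    gradients are recorded.  Either way the returned archive holds the
    gradient of the (mean-reduced) batch loss w.r.t. every gate weight for
    every batch of every epoch.
    """
    from .models import make_optimizer  # local import: models depends on data only

    if dataset.n_instances == 0:
        raise DatasetError("empty dataset")
    t, c = dataset.time_steps, dataset.channels
    if ext.mode == MODE_CHANNEL:
        if ext.weights.shape[0] != c:
            raise DimensionError(
                f"gate expects {ext.weights.shape[0]} channels, dataset has {c}"
            )
    elif ext.weights.shape != (t, c):
        raise DimensionError(
            f"gate weights {ext.weights.shape} incompatible with windows ({t}, {c})"
        )

    rng = np.random.default_rng(config.seed)
    train_idx, val_idx = _stratified_split(dataset, config.split, config.seed)
    x_train, x_val = dataset.data[train_idx], dataset.data[val_idx]
    y_train, y_val = dataset.labels[train_idx], dataset.labels[val_idx]

    model = model_factory(rng)
    optim = make_optimizer(config.optimiser, config.learning_rate)

    n_train = len(train_idx)
    batch_size = min(config.batch_size, n_train)
    n_batches = -(-n_train // batch_size)  # ceil
    entries = np.zeros((config.epochs, n_batches) + ext.weights.shape)

    run = TrainingRun(
        model=model,
        extension=ext,
        archive=GradientArchive(entries=entries, mode=ext.mode),
        train_index=train_idx,
        val_index=val_idx,
    )

    for epoch in range(config.epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for b in range(n_batches):
            sel = order[b * batch_size : (b + 1) * batch_size]
            xb, yb = x_train[sel], y_train[sel]
            zb = apply_extension(ext, xb)
            probs, cache = model.forward(zb, rng=rng, train=True)
            loss, dlogits = model.loss_grad(probs, yb)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite training loss at epoch {epoch}", epoch=epoch
                )
            grads, dz = model.backward(cache, dlogits)
            entries[epoch, b] = pairwise_gradient(ext, xb, dz)
            if ext.trainable:
                grads = dict(grads)
                grads["__gate__"] = entries[epoch, b]
                params = dict(model.params)
                params["__gate__"] = ext.weights
                optim.step(params, grads)
            else:
                optim.step(model.params, grads)
            epoch_loss += loss * len(sel)
        run.train_loss.append(epoch_loss / n_train)
        val_probs, _ = model.forward(apply_extension(ext, x_val), rng=None, train=False)
        run.val_loss.append(model.loss_grad(val_probs, y_val)[0])
    return run
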