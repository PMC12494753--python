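"""Importance scores and rankings from gate weights and gradient archives.

A gradient profile is, per feature, the sequence over training epochs of an
epoch-level aggregate of that feature's per-batch gate-weight gradients:
the within-epoch sum (for the AUC/ROC scores) or the within-epoch sample
standard deviation across batches (for the STD score).  Scores are:

* ``weight_naive`` — |final gate weights| (trainable gate),
* ``grad_auc``     — |trapezoid area under the sum profile|,
* ``grad_roc``     — |trapezoid area under the first differences of the sum
  profile, with the first epoch's value retained as element one|,
* ``grad_std``     — trapezoid area under the std profile (non-negative by
  construction, no absolute value taken).

Rankings are descending by score with ties broken by ascending feature index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import DimensionError
from .extension import MODE_CHANNEL, MODE_MATRIX, GradientArchive, PairwiseExtension

__all__ = [
    "AXIS_CHANNEL",
    "AXIS_TIME_STEP",
    "AXIS_CELL",
    "GRAD_METHODS",
    "GradientProfile",
    "ImportanceEstimate",
    "weight_naive_scores",
    "build_profile",
    "auc",
    "roc",
    "grad_scores",
    "ahp_aggregate",
    "save_estimate",
]

AXIS_CHANNEL = "channel"
AXIS_TIME_STEP = "time_step"
AXIS_CELL = "time_channel_cell"

GRAD_METHODS = ("grad_auc", "grad_roc", "grad_std")


def _ranking(scores: np.ndarray) -> np.ndarray:
    # stable sort on negated scores: descending, ascending-index tie-break
    return np.argsort(-scores, kind="stable")


@dataclass
class GradientProfile:
    """Per-feature epoch sequence of aggregated gate gradients."""

    values: np.ndarray  # (epochs, features)
    gamma: str  # "sum" | "std"
    feature_axis: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DimensionError("profile values must be (epochs, features)")


@dataclass
class ImportanceEstimate:
    """Non-negative per-feature scores with a descending ranking."""

    scores: np.ndarray
    method: str
    feature_axis: str
    feature_shape: tuple[int, ...] | None = None
    ranking: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64).ravel()
        self.ranking = _ranking(self.scores)

    @property
    def n_features(self) -> int:
        return self.scores.size

    def as_matrix(self) -> np.ndarray:
        """Cell scores reshaped to t' x c (cell estimates only)."""
        if self.feature_shape is None or len(self.feature_shape) != 2:
            raise DimensionError("estimate does not carry a t' x c layout")
        return self.scores.reshape(self.feature_shape)


def weight_naive_scores(ext: PairwiseExtension) -> ImportanceEstimate:
    """Importance from the trained gate weights' absolute magnitudes."""
    weights = np.asarray(ext.weights)
    if np.all(weights == weights.ravel()[0]):
        warnings.warn(
            "all gate weights are equal (untrained gate?); the ranking is "
            "degenerate and reflects only the index tie-break",
            stacklevel=2,
        )
    axis = AXIS_CHANNEL if ext.mode == MODE_CHANNEL else AXIS_CELL
    return ImportanceEstimate(
        scores=np.abs(weights).ravel(),
        method="weight_naive",
        feature_axis=axis,
        feature_shape=weights.shape if weights.ndim == 2 else None,
    )


def _entries_per_feature(archive: GradientArchive, feature_axis: str) -> np.ndarray:
    """Reduce archive entries to (epochs, batches, features) for the axis.

    A matrix-mode archive asked for channel features is first summed over the
    time axis (the channel-gate gradient is mathematically the time-sum of
    cell gradients); symmetrically for time-step features the channel axis is
    summed.
    """
    e = archive.entries
    if archive.mode == MODE_CHANNEL:
        if feature_axis != AXIS_CHANNEL:
            raise DimensionError(
                f"channel-mode archive only supports feature_axis={AXIS_CHANNEL!r}"
            )
        return e
    if feature_axis == AXIS_CELL:
        return e.reshape(e.shape[0], e.shape[1], -1)
    if feature_axis == AXIS_CHANNEL:
        return e.sum(axis=2)
    if feature_axis == AXIS_TIME_STEP:
        return e.sum(axis=3)
    raise DimensionError(f"unknown feature_axis {feature_axis!r}")


def build_profile(
    archive: GradientArchive, gamma: str, feature_axis: str = AXIS_CHANNEL
) -> GradientProfile:
    """Aggregate per-batch gradients into a per-epoch profile."""
    if archive.entries.size == 0:
        raise DimensionError("archive is empty")
    per_batch = _entries_per_feature(archive, feature_axis)
    if gamma == "sum":
        values = per_batch.sum(axis=1)
    elif gamma == "std":
        if per_batch.shape[1] < 2:
            warnings.warn(
                "gamma='std' with a single batch per epoch yields a zero profile",
                stacklevel=2,
            )
            values = np.zeros((per_batch.shape[0], per_batch.shape[2]))
        else:
            values = per_batch.std(axis=1, ddof=1)
    else:
        raise ValueError(f"gamma must be 'sum' or 'std'; got {gamma!r}")
    return GradientProfile(values=values, gamma=gamma, feature_axis=feature_axis)


def auc(profile_values) -> float:
    """Trapezoid area with unit epoch spacing; a length-1 profile is its value."""
    v = np.asarray(profile_values, dtype=np.float64)
    if v.ndim != 1 or v.size == 0:
        raise DimensionError("auc expects a non-empty 1-d sequence")
    if v.size == 1:
        return float(v[0])
    return float(np.trapezoid(v))


def roc(profile_values) -> np.ndarray:
    """First differences with the first epoch's value retained as element one."""
    v = np.asarray(profile_values, dtype=np.float64)
    if v.ndim != 1 or v.size < 2:
        raise DimensionError("roc expects a 1-d sequence of length >= 2")
    return np.concatenate([v[:1], np.diff(v)])


def grad_scores(
    archive: GradientArchive, method: str, feature_axis: str = AXIS_CHANNEL
) -> ImportanceEstimate:
    """Score features from a completed run's gradient archive."""
    if method not in GRAD_METHODS:
        raise ValueError(f"method must be one of {GRAD_METHODS}; got {method!r}")
    gamma = "std" if method == "grad_std" else "sum"
    profile = build_profile(archive, gamma=gamma, feature_axis=feature_axis)
    values = profile.values  # (epochs, features)
    if method == "grad_roc" and values.shape[0] < 2:
        raise DimensionError("grad_roc needs at least 2 epochs")
    scores = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        seq = values[:, j]
        if method == "grad_auc":
            scores[j] = abs(auc(seq))
        elif method == "grad_roc":
            scores[j] = abs(auc(roc(seq)))
        else:  # grad_std: std profiles are >= 0, no absolute value
            scores[j] = auc(seq)
    shape = None
    if feature_axis == AXIS_CELL:
        shape = archive.feature_shape
    return ImportanceEstimate(
        scores=scores, method=method, feature_axis=feature_axis, feature_shape=shape
    )


def ahp_aggregate(
    cell_estimate: ImportanceEstimate, window_steps: int, channels: int
) -> ImportanceEstimate:
    """Reduce per-cell scores to per-channel scores by the mean over time."""
    if cell_estimate.feature_axis != AXIS_CELL:
        raise DimensionError("ahp_aggregate requires a time_channel_cell estimate")
    if cell_estimate.scores.size != window_steps * channels:
        raise DimensionError(
            f"cell scores of size {cell_estimate.scores.size} do not reshape to "
            f"{window_steps} x {channels}"
        )
    cells = cell_estimate.scores.reshape(window_steps, channels)
    return ImportanceEstimate(
        scores=cells.mean(axis=0),
        method=cell_estimate.method,
        feature_axis=AXIS_CHANNEL,
    )


def save_estimate(
    estimate: ImportanceEstimate,
    path: str | Path,
    channel_names: list[str] | None = None,
    run_seed: int | None = None,
) -> Path:
    """Write scores/ranking as delimited text with a header."""
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = estimate.n_features
    if channel_names is not None and estimate.feature_axis == AXIS_CHANNEL:
        labels = list(channel_names)
    elif estimate.feature_shape is not None:
        t, c = estimate.feature_shape
        labels = [f"t{i // c}_c{i % c}" for i in range(n)]
    else:
        labels = [f"f{i}" for i in range(n)]
    rank_of = np.empty(n, dtype=int)
    rank_of[estimate.ranking] = np.arange(n)
    frame = pd.DataFrame(
        {
            "feature_id": np.arange(n),
            "feature_label": labels,
            "method": estimate.method,
            "score": estimate.scores,
            "rank": rank_of,
            "run_seed": run_seed if run_seed is not None else -1,
        }
    )
    frame.to_csv(path, index=False)
    return path
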