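"""Verification harness: Leave-One-Out / Singleton retraining and the
architecture-removal baseline comparison.

``run_ablation`` retrains the host model from scratch on every LOO subset
(one channel removed) and every Singleton subset (one channel kept), with
``config.runs`` seeded repetitions each — exactly ``2 * c * runs`` subset
retrains.  A channel whose removal hurts most (argmin LOO F1) and whose lone
retention helps most (argmax Singleton F1) is the ablation-designated
important channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import TimeSeriesDataset
from .exceptions import SubsetError, TrainingError
from .extension import make_extension, MODE_CHANNEL
from .models import TrainingConfig, fit
from .stats import compare, PairedComparison

__all__ = [
    "AblationTable",
    "loo_subset",
    "singleton_subset",
    "run_ablation",
    "architecture_ablation",
    "ArchitectureAblation",
]


def _channel_subset(dataset: TimeSeriesDataset, keep: np.ndarray) -> TimeSeriesDataset:
    mask = None if dataset.truth_mask is None else dataset.truth_mask[:, keep]
    if mask is not None and not mask.any():
        mask = None  # e.g. a noise-only singleton: no important cell remains
    return TimeSeriesDataset(
        data=dataset.data[:, :, keep],
        labels=dataset.labels,
        class_count=dataset.class_count,
        truth_mask=mask,
        channel_names=[dataset.channel_names[j] for j in keep],
    )


def loo_subset(dataset: TimeSeriesDataset, channel: int) -> TimeSeriesDataset:
    """Dataset with the named channel removed (needs c >= 2)."""
    c = dataset.channels
    if c < 2:
        raise SubsetError("cannot leave a channel out of a single-channel dataset")
    if not 0 <= channel < c:
        raise SubsetError(f"channel {channel} out of range [0, {c - 1}]")
    keep = np.array([j for j in range(c) if j != channel])
    return _channel_subset(dataset, keep)


def singleton_subset(dataset: TimeSeriesDataset, channel: int) -> TimeSeriesDataset:
    """Dataset reduced to the named channel only."""
    if not 0 <= channel < dataset.channels:
        raise SubsetError(
            f"channel {channel} out of range [0, {dataset.channels - 1}]"
        )
    return _channel_subset(dataset, np.array([channel]))


@dataclass
class AblationTable:
    """Per-channel LOO and Singleton weighted-F1 across seeded retrains."""

    channel_names: list[str]
    loo_f1: np.ndarray  # (channels, runs); NaN marks a diverged retrain
    singleton_f1: np.ndarray  # (channels, runs)
    baseline_f1: np.ndarray  # (runs,)
    runs: int
    retrain_count: int

    @property
    def loo_mean(self) -> np.ndarray:
        return np.nanmean(self.loo_f1, axis=1)

    @property
    def singleton_mean(self) -> np.ndarray:
        return np.nanmean(self.singleton_f1, axis=1)

    @property
    def argmin_loo(self) -> int:
        return int(np.nanargmin(self.loo_mean))

    @property
    def argmax_singleton(self) -> int:
        return int(np.nanargmax(self.singleton_mean))

    def per_run_argmin_loo(self) -> np.ndarray:
        return np.nanargmin(self.loo_f1, axis=0)

    def per_run_argmax_singleton(self) -> np.ndarray:
        return np.nanargmax(self.singleton_f1, axis=0)

    def to_frame(self):
        """Table laid out Method x channels: one LOO row, one Singleton row."""
        import pandas as pd

        return pd.DataFrame(
            [self.loo_mean, self.singleton_mean],
            index=["LOO", "Singleton"],
            columns=self.channel_names,
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path)
        return path


def run_ablation(
    classifier_for_dataset,
    dataset: TimeSeriesDataset,
    config: TrainingConfig,
) -> AblationTable:
    """2 * channels * runs full retrains on LOO and Singleton subsets.

    ``classifier_for_dataset`` maps a (sub)dataset to a model factory, so the
    host architecture can adapt to the reduced channel count.  A diverging
    retrain is recorded as NaN with a warning, not raised.  Baselines (full
    channel set, one per run) are trained in addition to the subset count.
    """
    c = dataset.channels
    if c < 2:
        raise SubsetError("channel ablation needs at least 2 channels")
    runs = config.runs
    loo_f1 = np.full((c, runs), np.nan)
    singleton_f1 = np.full((c, runs), np.nan)
    baseline_f1 = np.full(runs, np.nan)
    retrains = 0

    def _train(sub: TimeSeriesDataset, seed: int) -> float:
        result = fit(
            classifier_for_dataset(sub), sub, config.with_seed(seed), ext=None
        )
        return result.f1_weighted

    for r in range(runs):
        seed = config.seed + r
        baseline_f1[r] = _train(dataset, seed)
        for j in range(c):
            for table, subset in (
                (loo_f1, loo_subset(dataset, j)),
                (singleton_f1, singleton_subset(dataset, j)),
            ):
                try:
                    table[j, r] = _train(subset, seed)
                except TrainingError as err:
                    warnings.warn(
                        f"retrain diverged (channel {j}, run {r}): {err}",
                        stacklevel=2,
                    )
                retrains += 1

    return AblationTable(
        channel_names=list(dataset.channel_names),
        loo_f1=loo_f1,
        singleton_f1=singleton_f1,
        baseline_f1=baseline_f1,
        runs=runs,
        retrain_count=retrains,
    )


@dataclass
class ArchitectureAblation:
    """Baseline vs trainable-gate vs immutable-gate F1, per run."""

    baseline_f1: np.ndarray
    trainable_f1: np.ndarray
    immutable_f1: np.ndarray
    immutable_diff_exactly_zero: bool
    comparison_trainable: PairedComparison | None = None
    runs: int = 0


def architecture_ablation(
    classifier_for_dataset,
    dataset: TimeSeriesDataset,
    config: TrainingConfig,
    mode: str = MODE_CHANNEL,
) -> ArchitectureAblation:
    """Compare F1 with no gate, a trainable gate and an immutable gate.

    Immutable-gate runs share seeds with the baseline, so their F1
    difference is exactly zero by the identity-forward property; the
    trainable-vs-baseline contrast gets a paired test when runs >= 2.
    """
    runs = config.runs
    baseline = np.empty(runs)
    trainable = np.empty(runs)
    immutable = np.empty(runs)
    factory = classifier_for_dataset(dataset)
    for r in range(runs):
        cfg = config.with_seed(config.seed + r)
        baseline[r] = fit(factory, dataset, cfg, ext=None).f1_weighted
        ext_t = make_extension(dataset.time_steps, dataset.channels, mode, trainable=True)
        trainable[r] = fit(factory, dataset, cfg, ext=ext_t).f1_weighted
        ext_i = make_extension(dataset.time_steps, dataset.channels, mode, trainable=False)
        immutable[r] = fit(factory, dataset, cfg, ext=ext_i).f1_weighted

    record = ArchitectureAblation(
        baseline_f1=baseline,
        trainable_f1=trainable,
        immutable_f1=immutable,
        immutable_diff_exactly_zero=bool(np.array_equal(baseline, immutable)),
        runs=runs,
    )
    if runs < 2:
        warnings.warn("paired test refused: needs at least 2 runs", stacklevel=2)
        return record
    try:
        record.comparison_trainable = compare(trainable, baseline)
    except Exception as err:  # degenerate variance — report, don't fail
        warnings.warn(f"trainable-vs-baseline test refused: {err}", stacklevel=2)
    return record
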