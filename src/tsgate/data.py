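"""Labelled windowed time-series container and its on-disk representation.

The canonical array layout is ``(instances n, time steps t, channels c)``.
Labels are either per-instance (shape ``(n,)``) or per-time-step (shape
``(n, t)``); the optional ground-truth mask marks important ``(time, channel)``
cells of the class templates and therefore has shape ``(t, c)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import DatasetError

__all__ = ["TimeSeriesDataset", "save_dataset", "load_dataset"]


@dataclass
class TimeSeriesDataset:
    """Instances x time steps x channels with labels and optional truth mask."""

    data: np.ndarray
    labels: np.ndarray
    class_count: int
    truth_mask: np.ndarray | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise DatasetError(
                f"data must be 3-d (instances, time steps, channels); got {self.data.shape}"
            )
        n, t, c = self.data.shape
        if self.labels.shape not in {(n,), (n, t)}:
            raise DatasetError(
                f"labels must have shape ({n},) or ({n}, {t}); got {self.labels.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int64)
        if self.labels.size == 0:
            raise DatasetError("dataset is empty")
        lab_min, lab_max = int(self.labels.min()), int(self.labels.max())
        if lab_min < 0 or lab_max >= self.class_count:
            raise DatasetError(
                f"labels must lie in [0, {self.class_count - 1}]; got range [{lab_min}, {lab_max}]"
            )
        present = np.unique(self.labels)
        if present.size < self.class_count:
            missing = sorted(set(range(self.class_count)) - set(present.tolist()))
            raise DatasetError(f"classes {missing} absent from labels")
        if self.truth_mask is not None:
            self.truth_mask = np.asarray(self.truth_mask, dtype=bool)
            if self.truth_mask.shape != (t, c):
                raise DatasetError(
                    f"truth_mask must have shape ({t}, {c}); got {self.truth_mask.shape}"
                )
            if not self.truth_mask.any():
                raise DatasetError("truth_mask has no true cell")
        if not self.channel_names:
            self.channel_names = [f"ch{j}" for j in range(c)]
        elif len(self.channel_names) != c:
            raise DatasetError(
                f"expected {c} channel names, got {len(self.channel_names)}"
            )

    # -- shape accessors -------------------------------------------------
    @property
    def n_instances(self) -> int:
        return self.data.shape[0]

    @property
    def time_steps(self) -> int:
        return self.data.shape[1]

    @property
    def channels(self) -> int:
        return self.data.shape[2]

    @property
    def per_step_labels(self) -> bool:
        return self.labels.ndim == 2

    def instance_labels(self) -> np.ndarray:
        """Per-instance label vector; modal label for per-step datasets."""
        if not self.per_step_labels:
            return self.labels
        # majority vote per instance, ties to the smaller class id
        counts = np.apply_along_axis(
            lambda row: np.bincount(row, minlength=self.class_count), 1, self.labels
        )
        return counts.argmax(axis=1)

    def subset_instances(self, index: np.ndarray) -> "TimeSeriesDataset":
        return TimeSeriesDataset(
            data=self.data[index],
            labels=self.labels[index],
            class_count=self.class_count,
            truth_mask=self.truth_mask,
            channel_names=list(self.channel_names),
        )

    def to_long_frame(self):
        """Long-format (instance, step, channel, value, label) table."""
        import pandas as pd

        n, t, c = self.data.shape
        inst, step, chan = np.meshgrid(
            np.arange(n), np.arange(t), np.arange(c), indexing="ij"
        )
        labels = (
            self.labels[inst.ravel(), step.ravel()]
            if self.per_step_labels
            else self.labels[inst.ravel()]
        )
        return pd.DataFrame(
            {
                "instance": inst.ravel(),
                "step": step.ravel(),
                "channel": chan.ravel(),
                "value": self.data.ravel(),
                "label": labels,
            }
        )


def save_dataset(dataset: TimeSeriesDataset, path: str | Path) -> Path:
    """Write a dataset to a compressed array archive with a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    members = {
        "data": dataset.data,
        "labels": dataset.labels,
        "class_count": np.asarray(dataset.class_count),
    }
    if dataset.truth_mask is not None:
        members["truth_mask"] = dataset.truth_mask
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    np.savez_compressed(path, **members)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "channel_names": dataset.channel_names,
                "shape": list(dataset.data.shape),
                "per_step_labels": dataset.per_step_labels,
            },
            indent=2,
        )
    )
    return path


def load_dataset(path: str | Path) -> TimeSeriesDataset:
    path = Path(path)
    with np.load(path) as npz:
        data = npz["data"]
        labels = npz["labels"]
        class_count = int(npz["class_count"])
        truth_mask = npz["truth_mask"] if "truth_mask" in npz.files else None
    sidecar = path.with_suffix(".json")
    channel_names: list[str] = []
    if sidecar.exists():
        channel_names = json.loads(sidecar.read_text()).get("channel_names", [])
    return TimeSeriesDataset(
        data=data,
        labels=labels,
        class_count=class_count,
        truth_mask=truth_mask,
        channel_names=channel_names,
    )
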