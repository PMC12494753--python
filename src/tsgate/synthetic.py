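"""Synthetic time-series classification benchmarks with known ground truth.

Four three-class benchmarks (300 instances per class, 1000 time steps,
Gaussian noise with sd 0.02 by default):

* ``uni_peaks``    — univariate; classes differ by the period where a smooth
  unit bump occurs (centres at 20%/50%/80% of the series, width 10%).
* ``uni_patterns`` — univariate; classes differ by waveform (sine, square,
  triangle) over a shared active region.
* ``multi_0``      — 3 channels; channel 0 is pure noise, channel 1 carries a
  class-specific bump position (fully discriminative), channel 2 a weaker
  bump for class 2 only (partially discriminative).
* ``multi_1``      — 3 channels; channel 0 pure noise; classes 0 and 1 are
  distinguished by different waveforms in channel 1, class 2 by a bump in
  channel 2 only (its channel-1 content duplicates class 0's).

Every generator attaches a ``t x c`` boolean truth mask marking the cells
where class templates actually differ, so importance estimates can be scored
against ground truth without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .data import TimeSeriesDataset
from .exceptions import DimensionError, SpecError

__all__ = [
    "SyntheticSpec",
    "generate",
    "class_templates",
    "gen_univariate_peaks",
    "gen_univariate_patterns",
    "gen_multivariate",
    "per_step_labels",
    "window_dataset",
    "KINDS",
]

KINDS = ("uni_peaks", "uni_patterns", "multi_0", "multi_1")


@dataclass
class SyntheticSpec:
    kind: str
    samples_per_class: int = 300
    time_steps: int = 1000
    noise_sd: float = 0.02
    seed: int = 0
    class_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SpecError(f"kind must be one of {KINDS}; got {self.kind!r}")
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be > 0")
        if self.samples_per_class < 1 or self.time_steps < 1:
            raise SpecError("samples_per_class and time_steps must be >= 1")


def _bump(t: int, centre: float, width: float) -> np.ndarray:
    """Smooth unit-amplitude bump (Hann window) centred at a fraction of t."""
    series = np.zeros(t)
    half = max(int(round(width * t / 2)), 1)
    mid = int(round(centre * t))
    lo, hi = max(mid - half, 0), min(mid + half, t)
    series[lo:hi] = np.hanning(hi - lo)
    return series


def _active_window(t: int, lo_frac: float, hi_frac: float) -> slice:
    return slice(int(round(lo_frac * t)), int(round(hi_frac * t)))


def _waveform(name: str, phase: np.ndarray) -> np.ndarray:
    if name == "sine":
        return np.sin(phase)
    if name == "square":
        return _signal.square(phase)
    if name == "triangle":
        return _signal.sawtooth(phase, width=0.5)
    raise SpecError(f"unknown waveform {name!r}")


def _mask_from_templates(templates: np.ndarray, tol: float) -> np.ndarray:
    """Cells where any two class templates differ by more than tol."""
    k = templates.shape[0]
    mask = np.zeros(templates.shape[1:], dtype=bool)
    for a in range(k):
        for b in range(a + 1, k):
            mask |= np.abs(templates[a] - templates[b]) > tol
    return mask


# -- template builders: (templates (k, t, c), mask (t, c), channel names) ---


def _build_uni_peaks(spec: SyntheticSpec):
    t = spec.time_steps
    centres = spec.class_params.get("centres", (0.2, 0.5, 0.8))
    width = spec.class_params.get("width", 0.1)
    half = width / 2
    for a in range(len(centres)):
        for b in range(a + 1, len(centres)):
            if abs(centres[a] - centres[b]) < width:
                raise SpecError(
                    f"class peak windows overlap: centres {centres[a]} and "
                    f"{centres[b]} closer than width {width}"
                )
    templates = np.stack([_bump(t, c0, width)[:, None] for c0 in centres])
    mask = np.zeros((t, 1), dtype=bool)
    for c0 in centres:
        win = _active_window(t, max(c0 - half, 0.0), min(c0 + half, 1.0))
        mask[win, 0] = True
    return templates, mask, ["signal"]


def _build_uni_patterns(spec: SyntheticSpec):
    t = spec.time_steps
    waveforms = spec.class_params.get("waveforms", ("sine", "square", "triangle"))
    cycles = spec.class_params.get("cycles", 5)
    region = spec.class_params.get("region", (0.1, 0.9))
    amplitude = spec.class_params.get("amplitude", 1.0)
    if len(set(waveforms)) != len(waveforms):
        raise SpecError("waveforms must be distinct across classes")
    win = _active_window(t, *region)
    length = win.stop - win.start
    phase = 2.0 * np.pi * cycles * np.arange(length) / length
    templates = np.zeros((len(waveforms), t, 1))
    for k, name in enumerate(waveforms):
        templates[k, win, 0] = amplitude * _waveform(name, phase)
    if np.allclose(templates, 0.0):
        raise SpecError("zero-amplitude waveforms leave classes indistinguishable")
    mask = _mask_from_templates(templates, spec.noise_sd)
    if not mask.any():
        raise SpecError("class templates are indistinguishable above the noise floor")
    return templates, mask, ["signal"]


def _build_multivariate(spec: SyntheticSpec):
    t = spec.time_steps
    channels = spec.class_params.get("channels", 3)
    if channels < 3:
        raise SpecError(f"{spec.kind} needs at least 3 channels; got {channels}")
    templates = np.zeros((3, t, channels))
    if spec.kind == "multi_0":
        # channel 1 dominates: class-specific bump positions separate all
        # three classes.  channel 2 is only partially informative (a weaker
        # bump for class 2 alone).  channel 0 stays silent.
        centres = spec.class_params.get("centres", (0.2, 0.5, 0.8))
        for k in range(3):
            templates[k, :, 1] = _bump(t, centres[k], 0.1)
        templates[2, :, 2] = 0.5 * _bump(t, 0.5, 0.15)
    else:  # multi_1
        # classes 0/1: different waveforms in channel 1; class 2: channel-1
        # content duplicates class 0, distinguished by a channel-2 bump only.
        win = _active_window(t, 0.3, 0.7)
        length = win.stop - win.start
        phase = 2.0 * np.pi * 4 * np.arange(length) / length
        templates[0, win, 1] = np.sin(phase)
        templates[1, win, 1] = _signal.square(phase)
        templates[2, win, 1] = templates[0, win, 1]
        templates[2, :, 2] = _bump(t, 0.5, 0.2)
    mask = _mask_from_templates(templates, spec.noise_sd)
    mask[:, 0] = False  # channel 0 carries no class information by construction
    return templates, mask, [f"ch{j}" for j in range(channels)]


_BUILDERS = {
    "uni_peaks": _build_uni_peaks,
    "uni_patterns": _build_uni_patterns,
    "multi_0": _build_multivariate,
    "multi_1": _build_multivariate,
}


def _assemble(spec: SyntheticSpec) -> TimeSeriesDataset:
    """Stack per-class templates into instances and add seeded noise."""
    templates, mask, names = _BUILDERS[spec.kind](spec)
    rng = np.random.default_rng(spec.seed)
    k, t, c = templates.shape
    n = k * spec.samples_per_class
    labels = np.repeat(np.arange(k), spec.samples_per_class)
    data = templates[labels] + rng.normal(0.0, spec.noise_sd, size=(n, t, c))
    return TimeSeriesDataset(
        data=data,
        labels=labels,
        class_count=k,
        truth_mask=mask,
        channel_names=names,
    )


def class_templates(spec: SyntheticSpec) -> np.ndarray:
    """Noise-free class templates with shape (classes, t, c)."""
    return _BUILDERS[spec.kind](spec)[0]


def gen_univariate_peaks(spec: SyntheticSpec) -> TimeSeriesDataset:
    """Classes place a unit bump in class-specific non-overlapping windows."""
    if spec.kind != "uni_peaks":
        raise SpecError(f"spec.kind must be 'uni_peaks'; got {spec.kind!r}")
    return _assemble(spec)


def gen_univariate_patterns(spec: SyntheticSpec) -> TimeSeriesDataset:
    """Classes use distinct waveforms over a shared active region."""
    if spec.kind != "uni_patterns":
        raise SpecError(f"spec.kind must be 'uni_patterns'; got {spec.kind!r}")
    return _assemble(spec)


def gen_multivariate(spec: SyntheticSpec) -> TimeSeriesDataset:
    """Three-channel benchmarks with channel 0 as a pure noise channel."""
    if spec.kind not in {"multi_0", "multi_1"}:
        raise SpecError(f"spec.kind must be 'multi_0' or 'multi_1'; got {spec.kind!r}")
    return _assemble(spec)


def generate(spec: SyntheticSpec) -> TimeSeriesDataset:
    """Dispatch on ``spec.kind``."""
    return _assemble(spec)


def per_step_labels(dataset: TimeSeriesDataset) -> TimeSeriesDataset:
    """Broadcast per-instance labels to every time step (E3/E4-style shape)."""
    if dataset.per_step_labels:
        return dataset
    labels = np.repeat(dataset.labels[:, None], dataset.time_steps, axis=1)
    return TimeSeriesDataset(
        data=dataset.data,
        labels=labels,
        class_count=dataset.class_count,
        truth_mask=dataset.truth_mask,
        channel_names=list(dataset.channel_names),
    )


def window_dataset(
    dataset: TimeSeriesDataset, window: int, stride: int = 1
) -> TimeSeriesDataset:
    """Slide fixed-length windows over every instance.

    Per-time-step labels are sliced with the window; per-instance labels are
    copied to every window.  Windows per series: ``(t - window) // stride + 1``.
    The global truth mask does not transfer to overlapping windows and is
    dropped.
    """
    t = dataset.time_steps
    if window < 1 or stride < 1:
        raise DimensionError("window and stride must be >= 1")
    if window > t:
        raise DimensionError(f"window {window} exceeds series length {t}")
    starts = np.arange(0, t - window + 1, stride)
    data = np.stack(
        [dataset.data[:, s : s + window, :] for s in starts], axis=1
    ).reshape(-1, window, dataset.channels)
    if dataset.per_step_labels:
        labels = np.stack(
            [dataset.labels[:, s : s + window] for s in starts], axis=1
        ).reshape(-1, window)
    else:
        labels = np.repeat(dataset.labels, len(starts))
    return TimeSeriesDataset(
        data=data,
        labels=labels,
        class_count=dataset.class_count,
        truth_mask=None,
        channel_names=list(dataset.channel_names),
    )
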