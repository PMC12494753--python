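"""F1 metrics and the performance-comparison tests.

Two score sequences are compared with a paired t-test when their sample
standard deviations are similar (ratio within (1/2, 2)) and with Welch's
two-sample test otherwise.  Two-sided p-values throughout.  Family-level
multiple-comparison handling attaches the Bonferroni threshold ``0.05 / n``
and Holm step-down adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .exceptions import StatsError

__all__ = [
    "PairedComparison",
    "f1_scores",
    "compare",
    "compare_family",
    "holm_adjust",
]


@dataclass
class PairedComparison:
    a: np.ndarray
    b: np.ndarray
    t_stat: float
    dof: float
    p_value: float
    test_used: str  # "paired" | "welch"
    alpha_bonferroni: float | None = None
    p_holm: float | None = None


def f1_scores(predictions, labels, classes: int):
    """Weighted and per-class F1; absent classes score 0 with a warning."""
    from sklearn.metrics import f1_score

    predictions = np.asarray(predictions).ravel()
    labels = np.asarray(labels).ravel()
    if predictions.size == 0 or labels.size == 0:
        raise ValueError("empty predictions or labels")
    if predictions.shape != labels.shape:
        raise ValueError(
            f"predictions and labels must have equal length; got "
            f"{predictions.size} and {labels.size}"
        )
    all_classes = np.arange(classes)
    present = np.unique(labels)
    if present.size < classes:
        missing = sorted(set(all_classes.tolist()) - set(present.tolist()))
        warnings.warn(
            f"classes {missing} absent from labels; their F1 is reported as 0",
            stacklevel=2,
        )
    per_class = f1_score(
        labels, predictions, labels=all_classes, average=None, zero_division=0
    )
    weighted = f1_score(
        labels, predictions, labels=all_classes, average="weighted", zero_division=0
    )
    return float(weighted), np.asarray(per_class, dtype=np.float64)


def compare(a, b) -> PairedComparison:
    """Paired t-test, or Welch's test when the sd ratio leaves (1/2, 2)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1 or a.size != b.size:
        raise StatsError("compare expects two equal-length 1-d sequences")
    n = a.size
    if n < 2:
        raise StatsError("paired comparison needs at least 2 pairs")
    if np.array_equal(a, b):
        # identical samples: no difference, by convention t = 0, p = 1
        return PairedComparison(
            a=a, b=b, t_stat=0.0, dof=float(n - 1), p_value=1.0, test_used="paired"
        )
    sd_a, sd_b = a.std(ddof=1), b.std(ddof=1)
    similar_variance = sd_b > 0 and 0.5 < sd_a / sd_b < 2.0
    if similar_variance:
        d = a - b
        if d.std(ddof=1) == 0:
            raise StatsError("zero variance of paired differences; test refused")
        res = _stats.ttest_rel(a, b)
        return PairedComparison(
            a=a,
            b=b,
            t_stat=float(res.statistic),
            dof=float(res.df),
            p_value=float(res.pvalue),
            test_used="paired",
        )
    res = _stats.ttest_ind(a, b, equal_var=False)
    return PairedComparison(
        a=a,
        b=b,
        t_stat=float(res.statistic),
        dof=float(res.df),
        p_value=float(res.pvalue),
        test_used="welch",
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1:
        raise StatsError("holm_adjust expects a 1-d sequence")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


def compare_family(pairs: list[tuple], alpha: float = 0.05) -> list[PairedComparison]:
    """Run a family of comparisons and attach Bonferroni/Holm corrections."""
    if not pairs:
        return []
    results = [compare(a, b) for a, b in pairs]
    n = len(results)
    adjusted = holm_adjust([r.p_value for r in results])
    for r, ph in zip(results, adjusted):
        r.alpha_bonferroni = alpha / n
        r.p_holm = float(ph)
    return results
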