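"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import tsgate as tg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_multi0():
    """Small 3-channel benchmark: channel 0 noise, channel 1 dominant."""
    spec = tg.SyntheticSpec(kind="multi_0", samples_per_class=30, time_steps=120, seed=7)
    return tg.generate(spec)


@pytest.fixture
def tiny_config():
    return tg.TrainingConfig(epochs=5, batch_size=16, seed=11, runs=1)


def bare_training_oracle(dataset, config, classes):
    """Extension-free training loop, written independently of the package's
    trainer: same split, init, shuffling and optimiser but no gate layer and
    no gradient collection.  Returns the final parameter dict."""
    from sklearn.model_selection import train_test_split

    idx = np.arange(dataset.n_instances)
    train_idx, _ = train_test_split(
        idx,
        train_size=config.split,
        stratify=dataset.instance_labels(),
        random_state=config.seed,
    )
    train_idx = np.sort(train_idx)
    x_train = dataset.data[train_idx]
    y_train = dataset.labels[train_idx]

    rng = np.random.default_rng(config.seed)
    d = dataset.time_steps * dataset.channels
    W = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, classes))
    b = np.zeros(classes)

    # Adam state
    mW, vW = np.zeros_like(W), np.zeros_like(W)
    mb, vb = np.zeros_like(b), np.zeros_like(b)
    beta1, beta2, eps, lr = 0.9, 0.999, 1e-8, config.learning_rate
    t = 0

    n = len(train_idx)
    bs = min(config.batch_size, n)
    n_batches = -(-n // bs)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for bi in range(n_batches):
            sel = order[bi * bs : (bi + 1) * bs]
            xb = x_train[sel].reshape(len(sel), -1)
            yb = y_train[sel]
            logits = xb @ W + b
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            probs = e / e.sum(axis=1, keepdims=True)
            dlog = probs.copy()
            dlog[np.arange(len(sel)), yb] -= 1.0
            dlog /= len(sel)
            gW = xb.T @ dlog
            gb = dlog.sum(axis=0)
            t += 1
            for p, g, m, v in ((W, gW, mW, vW), (b, gb, mb, vb)):
                m += (1.0 - beta1) * (g - m)
                v += (1.0 - beta2) * (g * g - v)
                p -= lr * (m / (1 - beta1**t)) / (np.sqrt(v / (1 - beta2**t)) + eps)
    return {"W": W, "b": b}


def brute_force_grad_scores(entries, mode, method, feature_axis):
    """First-principles recomputation of gradient-profile scores.

    Loops over raw archive entries; trapezoid integration written out
    explicitly.  Deliberately independent of tsgate.analysis.
    """
    entries = np.asarray(entries, dtype=np.float64)
    if mode == "channel_vector":
        assert feature_axis == "channel"
        per_batch = entries
    else:
        if feature_axis == "channel":
            per_batch = entries.sum(axis=2)
        elif feature_axis == "time_step":
            per_batch = entries.sum(axis=3)
        else:
            per_batch = entries.reshape(entries.shape[0], entries.shape[1], -1)
    epochs, batches, features = per_batch.shape

    def trap(v):
        if len(v) == 1:
            return v[0]
        total = 0.0
        for i in range(len(v) - 1):
            total += 0.5 * (v[i] + v[i + 1])
        return total

    scores = np.zeros(features)
    for f in range(features):
        if method == "grad_std":
            prof = [
                float(np.std(per_batch[e, :, f], ddof=1)) if batches > 1 else 0.0
                for e in range(epochs)
            ]
            scores[f] = trap(prof)
        else:
            prof = [float(per_batch[e, :, f].sum()) for e in range(epochs)]
            if method == "grad_auc":
                scores[f] = abs(trap(prof))
            else:  # grad_roc
                seq = [prof[0]] + [prof[i] - prof[i - 1] for i in range(1, epochs)]
                scores[f] = abs(trap(seq))
    return scores
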