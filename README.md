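# tsgate

Channel and time-step importance estimation for time-series neural
classifiers via an **identity-initialised multiplicative gate layer**
inserted between the input window and a host network.  The gate's
training-time weight or gradient trajectories are analysed to score
features; a Leave-One-Out / Singleton retraining harness verifies the
estimates.

## How it works

A gate layer multiplies every input entry by a dedicated weight, all
initialised to exactly 1.0 (the identity function), in one of two modes:

- **channel vector** (`channel_vector`, "EWM"): one weight per channel,
  shared over time steps — yields per-channel importance;
- **time–channel matrix** (`time_channel_matrix`, Hadamard product): a full
  `t' x c` weight matrix — yields per-(time step, channel) cell importance,
  reducible to channel importance by averaging along the time axis ("AHP").

Training `NN(gate(x))` records the gradient of the loss with respect to every
gate weight, for every batch of every epoch, in a `GradientArchive`.  In
*immutable* mode the gate weights are never updated (the pipeline stays
bit-identical to the bare model); in *trainable* mode the gate is updated by
the same optimiser as the host model.  Scores:

| method         | definition                                                            |
|----------------|-----------------------------------------------------------------------|
| `weight_naive` | absolute magnitude of the trained gate weights                        |
| `grad_auc`     | abs. trapezoid area under the per-epoch **sum** gradient profile       |
| `grad_roc`     | abs. area under the epoch-to-epoch differences of the sum profile      |
| `grad_std`     | area under the per-epoch **batch standard deviation** profile          |

Everything runs on numpy (float64): the reference host networks (a shallow
flatten–linear–softmax classifier and a per-time-step LSTM), Adam/RMSprop
and backprop are implemented here with analytic gradients, validated against
finite differences in the test suite.  No deep-learning framework required.

## Layout

- `tsgate.extension` — gate layer, gradient collection, training loop
- `tsgate.analysis` — profiles, AUC/ROC/STD scores, AHP aggregation, rankings
- `tsgate.synthetic` — seeded benchmark generators with ground-truth masks
  (`uni_peaks`, `uni_patterns`, `multi_0`, `multi_1`), windowing helpers
- `tsgate.models` — host classifiers, optimisers, `TrainingConfig`, `fit`
- `tsgate.ablation` — LOO/Singleton retraining harness, architecture ablation
- `tsgate.stats` — weighted/per-class F1, paired/Welch t-tests, Bonferroni and
  Holm–Bonferroni corrections

## Quick start (API)

```python
import tsgate as tg

ds = tg.generate(tg.SyntheticSpec(kind="multi_0", seed=0))   # 900 x 1000 x 3
cfg = tg.TrainingConfig(epochs=30, batch_size=32, seed=0)
gate = tg.make_extension(ds.time_steps, ds.channels, tg.MODE_CHANNEL,
                         trainable=False)
factory = tg.shallow_softmax_classifier(ds.time_steps, ds.channels, 3)
run = tg.train_with_extension(factory, gate, ds, cfg)

est = tg.grad_scores(run.archive, "grad_auc")   # channel importance
print(est.scores, est.ranking)                  # noise channel 0 ranks last

table = tg.run_ablation(
    lambda d: tg.shallow_softmax_classifier(d.time_steps, d.channels, 3),
    ds, cfg)                                    # 2*c*runs retrains
print(table.to_frame())
```

## CLI

```bash
tsgate simulate --kind multi_0 --seed 0 --out data/multi0
tsgate run     --config config.yaml --mode ewm --out out/run0
tsgate ablate  --config config.yaml --out out/ablation
tsgate report  --run-dir out/run0 --out out/report
```

`config.yaml` holds the dataset spec (synthetic kind or file path), model
choice, training config, methods and seeds list; see `tests/test_cli.py` for
a minimal example.  Heatmaps are written both as PNG and as a plain-text
matrix normalised to [0, 1].

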