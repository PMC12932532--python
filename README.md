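# apneaformer

Per-second detection of obstructive sleep apnea (OSA) from a single-lead
overnight ECG, using a transformer encoder with a choice of positional
encodings — including a learnable, content-aware encoding produced by a
1-D convolutional autoencoder — plus a synthetic cohort generator that
makes the whole pipeline runnable without any clinical data.

## The problem

OSA produces discrete respiratory events (apneas and hypopneas, each
≥ 10 s) during sleep. Scoring overnight polysomnography by hand is slow
and expensive, and the ECG alone carries a usable signature: apnea imprints
a cyclic bradycardia–tachycardia pattern on the RR intervals between
heartbeats. The task here is fine-grained: given a 30-s ECG window
`x ∈ R^(30·fs)`, predict 30 binary labels, one per second, marking apnea
presence — not just a per-window verdict.

## The model

Raw windows are min-max normalized to [0, 1] (missing samples → 0) and fed,
after an additive positional encoding `Z_i = inputE(x_i) + PE(i)`, into a
stack of transformer encoder blocks. Each block applies

1. multi-head self-attention (4 heads of size 256), and
2. a pointwise-convolution feed-forward sublayer (128 filters, ReLU),

each enclosed by a residual connection and a subsequent layer
normalization. The encoder output is globally average-pooled and passed to
an MLP head (128 units) with a 30-unit sigmoid output — one apnea
probability per second. Training is class-weighted binary cross-entropy
(balanced weights `w_c = N / 2N_c` against the ≈ 0.17 apnea:normal second
imbalance) with AdamW (weight decay 1e-4), learning rate 1e-3 held for 10
epochs then decayed ×0.9/epoch to a floor of 1e-4.

Positional-encoding strategies (`posenc_strategy`):

| strategy      | PE(i)                                                  |
|---------------|--------------------------------------------------------|
| `none`        | no positional term                                     |
| `naive`       | normalized index `i / (L−1)`                           |
| `sinusoidal`  | sin/cos table of depth `d_model = 32`, learned input projection |
| `autoencoder` | conv(132) → dropout(0.1) → conv(64) → transposed conv, added element-wise |

The autoencoder variant is the interesting one: it is *content-aware* —
the encoding is a learned function of the waveform itself, not only of the
sample index — and it trains jointly with the classifier (or
self-supervised on reconstruction, then frozen).

All splits are at the patient level (80/20 hold-out, 5-fold grouped CV),
so no subject ever contributes to both training and evaluation.

The neural network (layers, attention, transposed convolution, AdamW) is
implemented in NumPy inside `apneaformer.nn`, with every backward pass
verified against finite differences in the test suite.

## The synthetic cohort

`generate_cohort` emulates the structure of a 30-patient clinical OSA
ECG dataset: severity quota 7/8/8/7 (none/mild/moderate/severe, AHI
intervals [0.5,4.5)/[5,15)/[15,30)/[30,60) events·h⁻¹), recordings of
7–12 h at 80 Hz, truncated-lognormal event durations (min 10 s, mean
26 s), a ±25 % sinusoidal RR modulation during events, Gaussian-pulse beat
morphology with 5 % additive noise, and 0.2 % missing samples. Those
defaults make the pooled apnea:normal second ratio come out at ≈ 0.17.

## Worked example

A desk-scale experiment — 6 moderate/severe subjects, ~45-min recordings
at 8 Hz, a 2-block model with the autoencoder encoding, 8 epochs on CPU:

```python
import numpy as np
from apneaformer import (SyntheticConfig, generate_cohort, preprocess_cohort,
                         ApneaTransformerClassifier, split_patients,
                         evaluate_predictions)

cfg = SyntheticConfig(
    n_subjects=6,
    severity_quota={"none": 0, "mild": 0, "moderate": 3, "severe": 3},
    duration_range=(0.7, 0.9),   # hours
    fs=8.0,                      # scaled-down sampling rate
    rr_modulation_depth=0.4,
    seed=11,
)
cohort = generate_cohort(cfg)
X, y, subjects, _ = preprocess_cohort(cohort)
print(f"{X.shape[0]} windows of {X.shape[1]} samples; "
      f"positive-second fraction {y.mean():.3f}")

plan = split_patients([r.subject_id for r in cohort], test_fraction=1/3, seed=0)
dev = np.isin(subjects.astype(str), plan.dev_subjects)

clf = ApneaTransformerClassifier(
    num_blocks=2, num_heads=2, head_size=32, ff_hidden=32,
    posenc_strategy="autoencoder", epochs=8, random_state=1)
clf.fit(X[dev], y[dev])

proba = clf.predict_proba(X[~dev])
report = evaluate_predictions((proba >= 0.5).astype(int), proba, y[~dev])
```

Output:

```
553 windows of 240 samples; positive-second fraction 0.241
accuracy     0.8973
sensitivity  0.7842
specificity  0.9269
precision    0.7369
f1           0.7599
auc          0.9449
event level  {'matched': 43, 'missed': 2, 'spurious': 101}
```

Read: on the two held-out subjects the model scores each second with AUC
0.94; 43 of 45 annotated events are hit by at least one detected run of
positive seconds. The spurious count is inflated by very short false runs —
`aggregate_events(mask, min_duration=10)` applies the clinical 10-s
minimum and prunes most of them. The same configuration with
`posenc_strategy="none"` reaches AUC ≈ 0.83: the content-aware encoding
earns its keep.

## Command line

```bash
apneaformer simulate   --config cohort.yaml --out DIR --seed 7
apneaformer preprocess --config run.yaml --cohort DIR --out dataset.npz
apneaformer train      --config run.yaml --data dataset.npz --out RUNDIR
apneaformer evaluate   --run RUNDIR --data dataset.npz --split test
apneaformer ablate     --config run.yaml --out ablation.csv   # five PE variants side by side
apneaformer run        --config run.yaml --out RUNDIR         # full pipeline
```

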