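# Methods

## Scope

The package detects obstructive-sleep-apnea events in single-lead ECG at
one-second resolution. It contains (i) a synthetic cohort generator that
emulates the statistical structure of a 30-patient clinical OSA dataset,
(ii) preprocessing that turns annotated recordings into 30-s windows with
30 per-second binary labels, (iii) a transformer-encoder classifier with
four interchangeable positional-encoding strategies, and (iv) training and
evaluation machinery with patient-level splits. Everything runs on CPU;
the neural network is implemented in NumPy with analytic backward passes.

## The synthetic cohort: what it emulates, and what it does not

The generator reproduces the *label and signal structure* a per-second
apnea detector must cope with, not ECG physiology:

- **Cohort composition.** 30 subjects by default, severity quota 7/8/8/7
  over AHI classes none [0.5, 4.5), mild [5, 15), moderate [15, 30),
  severe [30, 60) events·h⁻¹. Each subject draws a target AHI uniformly
  from its class interval and a duration uniformly from 7–12 h. The
  achieved AHI (event count / hours) is re-verified against the class
  interval, resampling on the rare rounding violation near a class edge.
- **Events.** Durations follow a lognormal (shape σ = 0.5) truncated below
  at the clinical 10-s minimum, with the scale solved in closed form so
  the truncated mean is 26 s. Placement distributes the free time into
  Dirichlet-random gaps with a 5-s minimum separation, which guarantees
  non-overlap by construction. Kinds are drawn 2:1 hypopnea:apnea; both
  map to the positive class, matching the binary task.
- **Calibration.** The quota implies a cohort-mean AHI of ≈ 19.75
  events·h⁻¹; at 26 s per event the expected positive-second fraction is
  19.75·26/3600 ≈ 0.143, i.e. an apnea:normal ratio of ≈ 0.17. Realized
  ratios vary by roughly ±0.015 across seeds from the AHI and duration
  draws.
- **Signal.** Beat times integrate an RR-interval process: baseline 0.9 s
  with Gaussian beat-to-beat jitter (SD 0.02 s, floor 0.2 s), and inside
  each event one full sinusoidal cycle of relative amplitude
  `rr_modulation_depth` (default 0.25) — the interval lengthens then
  shortens, the bradycardia–tachycardia signature of apnea. Each beat is
  rendered as a Gaussian pulse (σ = 30 ms, unit peak); noise is additive
  Gaussian with SD `noise_sd × peak` (default 0.05), and a uniform 0.2 %
  of samples are set missing (NaN; empty fields in CSV).

Deliberately absent: PQRST morphology, respiratory amplitude modulation,
arousals, desaturation, movement artefacts, and non-stationary noise. A
model that separates apnea seconds here has demonstrably learned to use
RR-interval structure under noise, missingness and class imbalance — it
has *not* been validated on clinical ECG, and the test metrics must not be
read as clinical performance.

For cohort-level label statistics the generator can skip waveform
rendering (`signals=False`); a full default cohort is ~8×10⁸ samples and
is only materialized on demand.

## Preprocessing conventions

- Min–max normalization to [0, 1] is computed **per recording** over the
  non-missing values first; missing samples are then set to 0; windowing
  comes last. Imputing before taking the min would corrupt the range. The
  ambiguity between per-recording and per-window scaling is kept behind
  `normalize_scope`; per-recording is the default.
- All times are 0-based with half-open intervals [start, end). A second
  `s` is labeled positive iff its **bin start** lies inside an event, so
  an event [a, b) marks seconds ceil(a)…ceil(b)−1 and contributes exactly
  ceil(b) − ceil(a) positives: event durations are preserved in whole
  seconds and never extended, and no isolated positives appear outside
  events. Events spanning a 30-s boundary label seconds in both windows.
- Trailing partial windows are dropped, not padded; padding would dilute
  the label grid with fabricated negatives.

## Model

Input tensor (batch, L, 1) with L = 30·fs. The encoder block is post-norm:
attention → dropout → +residual → layer norm, then pointwise conv
(ff_hidden = 128, ReLU) → dropout → pointwise conv restoring channels →
+residual → layer norm. Best published hyperparameters are the defaults:
6 blocks, 4 heads, head size 256 (read as the per-head key dimension),
MLP 128, dropout 0.1, batch 32, AdamW at 1e-3 with weight decay 1e-4.

Two conventions deserve explanation because the univariate input makes
the textbook choices degenerate:

- **Layer-norm axis.** Post-norm layer normalization over the channel axis
  of a single-channel sequence maps every value to the affine shift —
  the signal is annihilated. Normalization is therefore applied over the
  **time axis** (per-channel standardization across the window, affine
  per channel) by default; channel-axis normalization remains available
  (`norm_axis="channels"`) for multi-channel encodings.
- **Pooling axis.** `GlobalAveragePooling` over time would collapse each
  single-channel window to one scalar, making 30 distinct per-second
  outputs unlearnable. The default pools over **channels**, leaving one
  feature per time step for the MLP head; time pooling is available
  (`pool_axis="time"`), and with no positional encoding that variant is
  permutation-invariant in the samples — a property the tests assert.

The learning-rate schedule holds 1e-3 for 10 epochs, then multiplies by
0.9 per epoch, floored at 1e-4. The decay factor and floor are config
keys; the shape (constant, then exponential decay to a 1e-4 floor) is the
published behaviour, the factor 0.9 is this package's choice.

Weight initialization is uniform fan-in, fully seeded; with dropout
disabled the forward pass is a pure function, and all training
randomness (init, shuffling, dropout) derives from `random_state`.

## Positional encodings

- **naive**: `PE(i) = i/(L−1)`, added to the single channel.
- **sinusoidal**: the standard sin/cos table with
  `PE(pos, 2i) = sin(pos/10000^(2i/d_model))`, depth 32. Because the
  table has `d_model` channels and the signal one, the input first passes
  a learned pointwise projection to `d_model`. The table is generated at
  the full sequence length by default; a `tile64` mode instead linearly
  resamples a fixed 64-row table to the window length. Both readings of
  the published "length 64, depth 32" configuration are preserved.
- **autoencoder**: conv1d(132, k=7, ReLU) → dropout(0.1) → conv1d(64,
  k=7, ReLU) → transposed conv1d restoring one channel; stride 1 with
  'same' padding so output shape equals input shape for any length, which
  is what makes the element-wise addition well-typed. The kernel size 7
  and stride 1 are this package's choices (unspecified upstream). The
  reconstruction-shaped output (not the bottleneck activation) is what is
  added to the input, since the additive combination requires shape
  compatibility. Training is joint with the classification loss by
  default; a `pretrained` mode first fits the reconstruction objective
  self-supervised (targets = inputs) and freezes the component.

## Training and evaluation

- Balanced class weights `w_c = N/(2N_c)` equalize the weighted mass of
  apnea and normal seconds; with weights {1, 1} the loss equals plain
  binary cross-entropy to machine precision.
- Splits: seeded 80/20 subject-level hold-out; within the development set,
  5 disjoint validation folds (`nested`, default). A `paper_literal` mode
  draws five independent 23-train/7-validation splits over all subjects —
  the published arithmetic, which cannot be a disjoint partition of 30;
  its validation sets may recur across folds. The nested mode is the
  leakage-free protocol and is what the tests assert on.
- Second-level metrics come from the 2×2 confusion counts; undefined
  ratios are reported as NaN with a warning, never silently as 0. ROC-AUC
  is the trapezoidal area, micro-averaged over all pooled seconds of the
  evaluation set (the pooling level is a package choice).
- Event-level evaluation aggregates maximal runs of positive seconds into
  detected events and matches them to annotations by any-overlap, each
  annotated event matched at most once, greedily in start order. An
  overlap-fraction threshold and a minimum-duration filter (e.g. the
  clinical 10 s) are available and off by default.

## Problem sizes used in the tests

The suite exercises the full-size architecture only in forward mode
(shape and determinism contracts at L = 2400). Learning checks run a
scaled-down configuration chosen to finish in minutes on one CPU while
leaving the method intact: 6 subjects (3 moderate, 3 severe), ~45-min
recordings at fs = 8 Hz (L = 240), RR modulation depth 0.4, a 2-block
model with 2 heads of size 32, 8 epochs. Under those conditions the
held-out per-second AUC is ≈ 0.83 without positional encoding and ≈ 0.94
with the autoencoder encoding; the acceptance tests assert AUC ≥ 0.75 on
a majority of three seeds and non-inferiority (−0.05) of the autoencoder
variant. The published full-scale scores require the original clinical
recordings and are out of scope here.

## Known limitations

- The waveform model is a pulse train, not an ECG; results quantify
  methodology on controlled structure, not clinical accuracy.
- Attention is O(L²); full-rate windows (L = 2400) train impractically
  slowly on CPU. The architecture is rate-agnostic, so experiments use
  reduced sampling rates.
- `paper_literal` cross-validation is provided for comparability but can
  reuse validation subjects across folds by construction.
- Checkpointing stores raw parameter arrays plus the frozen YAML config;
  no cross-version compatibility is attempted.
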