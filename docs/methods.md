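# Methods

## Problem and model

`cbamhar` studies how lightweight attention changes a standard
sensor-based human activity recognition (HAR) pipeline.  The backbone is
the DeepConvLSTM hybrid: a window of `H` time steps by `D` sensor
signals is treated as a 2-D input, passed through four temporal
convolution layers (64 filters each; the kernel spans 5 samples along
time and 1 along the signal axis, valid padding, ReLU), the resulting 64
feature maps are flattened per time step into `64·D` features, fed to
two LSTM layers with 128 units, and the last time step's output drives a
softmax over the activity classes.

A convolutional block attention module (CBAM) refines an intermediate
feature map `X ∈ R^(C×H×W)` (here `C` = 64 filters, `H` = time, `W` =
signals) with two sigmoid-valued multiplicative masks:

* **Channel attention (CHatt)** — average- and max-pool `X` over all
  `(H, W)` positions into two length-`C` descriptors, push both through
  one *shared* bottleneck MLP (`C → C/r → C`, reduction ratio `r`), sum
  the outputs, apply a sigmoid, and scale each channel by its mask
  value.  Trainable scalars: `2·C·(C/r) + C + C/r` (both biases
  included; the count forces them).
* **Spatial attention (SPatt)** — average- and max-pool across channels
  into two `H×W` planes, stack them (average first), convolve with one
  `k×k` kernel (zero-padded, size-preserving, no bias — the `k·k·2`
  count forces bias-free), apply a sigmoid, and multiply every channel
  elementwise.  Masks are strictly inside `(0, 1)`, so attention always
  shrinks features and cannot flip signs.
* **CHSPatt** — channel first, then spatial; the spatial mask is
  computed from the channel-refined map, not the raw input.

Blocks can sit after any one of the four conv layers or after all four
(independent weights per layer, so "all" costs four times the
single-layer figure).  At `C = 64` the channel overheads for
`r = 1, 2, 4, 8, 16` are 8320, 4192, 2128, 1096, 580 scalars; the
spatial overheads for `k = 3, 5, 7` are 18, 50, 98; combined settings
are the sums.  These counts are exact structural facts and are verified
in three ways (closed form, instantiated attention modules, whole-model
count differences).

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| reduction ratio `r` | grid {1, 2, 4, 8, 16} | MLP bottleneck width `C/r`; must divide `C` (non-divisible values are rejected rather than floored) |
| kernel size `k` | grid {3, 5, 7} | spatial neighbourhood; must be odd (`k = 1` is accepted as a pointwise diagnostic but flagged non-canonical) |
| placement | {1, 2, 3, 4, all} | conv layer after whose ReLU the block is inserted |
| conv kernel (time) | 5 samples | with 4 valid convolutions a window loses 16 steps, so `H ≥ 17` |
| LSTM dropout | 0.0 | set to 0.5 for null-dominated gesture streams, which otherwise overfit |
| learning rate / batch | 0.001 / 64 | Adam with its usual defaults; categorical cross-entropy |
| epochs | 50 full runs, 10 grid-on-synthetic, 20 sanity benchmark | best-validation-macro-F1 checkpoint is restored when a validation split exists |

The experiment grid crosses the three modes with these values:
25 channel + 15 spatial + 75 combined = 115 attention settings next to
one baseline, named by the `w_CHattx(r)` / `w_SPattx(k)` /
`w_CHSPattx(r)(k)` grammar (`x` empty = all four layers).

## Design choices where the design was open

* **MLP hidden activation.**  The shared bottleneck MLP uses ReLU on the
  hidden layer (the common CBAM convention); it is switchable to
  identity (`mlp_hidden_activation`), since nothing in the parameter
  accounting depends on it.
* **Attention position relative to ReLU.**  Blocks are applied to the
  post-activation conv output.
* **Eq-level semantics.**  Masks act by elementwise multiplication; no
  residual connection is added around attention blocks.
* **Spatial padding.**  Zero padding keeps the mask at `H×W`; borders
  therefore see partial neighbourhoods.
* **Plane order.**  Average-pooled plane first, max-pooled second.
* **Max-pool gradients.**  Ties split the gradient equally among the
  tied entries (a measure-zero event for continuous inputs).
* **Window geometry.**  Windows default to about one second (50 samples
  at 50 Hz, 30 at 30 Hz) with 50% overlap; both are config keys.  A
  window is labelled by majority vote; ties go to the last time step's
  label.
* **Splits.**  The 60/20/20 train/test/val holdout and the stratified
  five-fold assignment operate window-wise (not subject-wise) on a
  canonical window identity (recording id, start sample), which makes
  assignments independent of storage order.  Subject-wise splitting
  would be stricter about inter-window leakage; results are labelled
  with the mode used.
* **Pamap2 cleaning.**  The ±16g accelerometer is used (config key);
  interior NaN runs are linearly interpolated and edges extended with
  the nearest value; 100 Hz → 50 Hz by plain decimation (keep every
  second sample).  Rows outside the 12 protocol activities are dropped,
  and each contiguous run of kept rows becomes its own recording so no
  window spans a gap.
* **Null class.**  For gesture streams the null/background class is an
  ordinary class: it appears in confusion matrices and contributes to
  macro F1.
* **Absent classes.**  A class absent from both truth and prediction
  contributes F1 = 0 to the macro mean (with a warning) — the
  conservative reading of an unweighted mean over a fixed inventory.
* **One-sample tests.**  Two-sided by default.  The sample is the 115
  attention scores tested against the baseline score as the population
  value; `include_baseline=True` exposes the alternative reading where
  the baseline is a 116th observation.
* **Base model totals.**  Published totals of 822,098 (gesture model)
  and 1,415,244 (daily-activity model) parameters depend on a window
  and flattening geometry that standard conventions do not reproduce,
  so the package reports its own backbone counts
  (`backbone_param_count`) and gates only the attention *deltas*, which
  are geometry-independent.  The published totals are still used as
  denominators when expressing overheads as percentages (0.006% and
  0.296% for the two headline settings).

## Numerical engine

The network, backprop and Adam are implemented directly on NumPy arrays
(`cbamhar.nn`): the temporal convolution is an im2col matrix product,
the spatial-attention convolution a strided sliding-window contraction,
and the LSTM a standard gate-caching loop (forget bias initialised
to 1).  Training runs in float32 by default; float64 is a config switch
and is what the finite-difference gradient tests use (every layer and
the full model agree with central differences to ~1e-6 relative).  The
single-map reference semantics in `cbamhar.attention` (float64, with the
spatial convolution delegated to `scipy.signal.correlate2d`) are the
ground truth the batched layers are tested against, and both routes are
checked against explicit-loop oracles.  Two builds from the same config
and seed are bitwise identical; training is deterministic given the
config and training seeds on a fixed BLAS.

## What the synthetic generator does and does not emulate

A synthetic recording is a sequence of labelled segments (durations
uniform within a configurable range); within a segment, each class
drives its own subset of informative signals with a class-specific
sinusoid (random phase per segment) plus Gaussian noise, while all other
signals carry pure noise.  Class proportions are configurable, including
a ~72%-null regime where the null class emits noise only.  This rewards
exactly the structures the model has: per-channel relevance (which
signals matter differs by class — channel attention), local temporal
structure (spatial attention), and periodicity (convolutions + LSTM).

It does **not** emulate gravity and orientation drift, amplitude
non-stationarity, inter-subject variability, label jitter at segment
boundaries, or cross-sensor correlation of real IMUs.  Passing the
training-sanity checks therefore shows the pipeline learns and the
attention blocks do not break optimisation — it does not predict
real-dataset scores, which require the UCI downloads and the shipped
`scripts/run_pamap2.py` / `scripts/run_opportunity.py` runs (hours on a
CPU).

Benchmark presets: `pamap2-like` (27 signals, 12 balanced classes,
50 Hz, 240 s), `opportunity-like` (45 signals, 17 gestures + 72% null,
30 Hz, 600 s), and `separable6` (9 signals, 6 classes, 30 Hz, 300 s,
noise_sd 0.08 with amplitude 1.0 — inside the regime where per-window
signal power is linearly separable, which keeps the end-to-end training
check well-posed).  The sanity check trains the full 64-filter /
128-unit backbone for up to 20 epochs on ~360 training windows; each
run takes tens of seconds on one CPU core.

## Known limitations

* Only the serial channel-then-spatial composition is implemented, not
  parallel or spatial-first arrangements.
* Window-wise splitting allows overlapping windows from one recording to
  land in different splits; use the run scripts' options or subject-level
  filtering when leakage matters.
* The NumPy engine is single-core and aimed at desk-scale experiments;
  full-dataset grid runs are CPU-hours.
* Decimation without an anti-alias filter is the default downsampler;
  contamination is negligible for the low-frequency content of interest
  but a filtered option is the right choice for high-frequency signals.
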