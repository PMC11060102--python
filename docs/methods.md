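# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic experiments can show.

## The continuous-pursuit task

The workspace is the unit square `[0, 1]^2` (origin bottom-left, x
rightward, y upward); all speeds are in arena units per second. Every
control tick (40 ms) the target receives a per-axis acceleration drawn from
`N(0, target_accel_sd^2)`, Euler-integrated (`v <- v + a * tick`); its speed
is clamped to `target_vmax` and its position to the arena. Within
`repulsion_zone` of an edge an extra acceleration of magnitude
`repulsion_accel` points back toward the interior, so the target does not
loiter on the boundary. Boundary contact zeroes the normal velocity
component (an inelastic stop — consistent with steering a physical object);
nothing wraps around.

Defaults (fast preset): `cursor_speed = 0.20/s`, `target_accel_sd =
0.5/s^2`, `target_vmax = 0.25/s`, `repulsion_zone = 0.1`, `repulsion_accel
= 1.0/s^2`, 60 s trials, 5 trials per run. These make a trial trackable but
not trivial. The slow preset derives from the fast one by the protocol's
stated reductions: cursor speed x0.75, acceleration variance x(2/3).
Session plans: the first CP session is 12 runs of the traditional decoder;
later sessions are three 4-run blocks (one per decoder) in a seeded random
order; every session appends one chance run.

## The synthetic subject

Intent is the unit cursor→target direction (the labeling direction). It is
mapped to hand-MI intensities by inverting the additive control model
`h = a_R − a_L`, `v = a_R + a_L − 1`:

    a_R = clip((h + v + 1)/2, 0, 1),   a_L = clip((v − h + 1)/2, 0, 1)

so right = right hand, up = both hands, down = rest, and the zero direction
(cursor on target) is the neutral hover (0.5, 0.5). Real users blend the
four commands in idiosyncratic ways; this inverse is one consistent,
deterministic choice.

Activations pass through a pure delay (`reaction_lag_s`, default 0.6 s) and
a first-order low-pass (`activation_smoothing_s`, default 0.3 s) — the
user's reaction time and the sluggishness of changing imagery. The EEG per
channel is

    x_c(t) = alpha_amp * A_c(t) * sin(2*pi*f_alpha*t + phi_c) + pink noise

with `A_c(t) = 1 − erd_depth * (g_C3(c) a_R(t) + g_C4(c) a_L(t))`,
activations held constant within a tick. The ERD gains `g` are Gaussian
kernels of great-circle distance to C3 (right hand) and C4 (left hand),
width `spatial_sigma = 0.5` rad. Defaults: `f_alpha = 10 Hz`, `alpha_amp =
10 µV`, pink-noise std 8 µV with 1/f slope 1.0, `erd_depth = 0.5` (0.6 in
the well-separated test subject). Channel geometry comes from the standard
extended 10/20 layout (64 channels), normalized to the unit sphere; a
16-channel sensorimotor subset serves the reduced-size configurations.

Intersession variability is modeled by `session_variant`: per session the
ERD depth gets an additive Gaussian shift (sd 0.15, clipped to [0.05, 1])
and the alpha peak frequency a jitter (sd 0.75 Hz). This is the generative
definition used wherever "a new day" is needed (notably midsession
recalibration experiments).

What the generator does **not** emulate: volume conduction and realistic
source mixing, eye/muscle artifacts, alpha bursting/nonstationarity within
a session, and — most importantly — a subject who *adapts to the decoder*.
Passing tests therefore demonstrate internal consistency of the pipeline on
idealized lateralized ERD, not performance on human EEG.

## Labeling and preprocessing

Labels are unit cursor→target vectors taken at the window's end tick
(causal). Windows: 1.0 s long, stride 0.2 s for training, sliding every
tick online; windows with cursor-target distance `< 0.02` are excluded
(direction numerically undefined near contact), as are windows overlapping
the first second of a trial (reaction-lag warm-up). Per-decoder features:

- `raw_downsampled` (EEGNet-style): 4–40 Hz band-pass (4th-order
  Butterworth, zero-phase within the window), decimation to 125 Hz,
  per-channel z-score over the window. Per-window z-scoring trades absolute
  amplitude for robustness to inter-session amplitude drift.
- `band_spectrum` (PointNet-style): per-channel Welch log-amplitude
  spectrum on 4–40 Hz at ~1 Hz resolution, concatenated with the
  electrode's 3D coordinates to form a 64-point cloud with 3+37 attributes.

## Decoders

**Traditional AR decoder.** Every tick, alpha-band (8–13 Hz) power at C3
and C4 is estimated from a 0.5 s trailing buffer by Burg AR(16) and
integrated from the AR spectrum. Control: `raw_h = log P(C4) − log P(C3)`,
`raw_v = −(log P(C3) + log P(C4))`, each axis z-scored by exponentially
weighted running statistics (half-life 30 s) and the vector clipped to the
unit disc. Log power is used because raw band power is strongly
right-skewed: z-scoring raw power leaves most samples below the running
mean and biases the vertical axis. The first 2 s of every trial emit zeros
while the buffer and statistics settle. The decoder needs no training data.

**EEGNet-style CNN.** Temporal convolution (F1 filters, kernel ≈ half the
125 Hz rate), depthwise spatial convolution across channels (D per filter,
max-norm 1 per filter), batch-norm + ELU + average-pool(4) + dropout, then
a separable convolution (depthwise temporal + pointwise to F2 = F1·D maps),
pool(8) + dropout, and a linear map to 2 outputs. Defaults F1=8, D=2,
F2=16, dropout 0.25; the reduced spec uses F1=4, F2=8. The output head
carries **no** max-norm cap: the canonical 0.25 cap regularizes
classification logits, but here the head regresses a direction vector whose
magnitude doubles as online cursor speed, and capping it pins the cursor at
a fraction of full speed.

**PointNet-style network.** Electrodes are a point cloud. Three set-
abstraction stages: farthest-point sampling of centroids (deterministic,
geometry-only: the start point and every tie are resolved by coordinates,
which makes the forward pass exactly invariant to electrode input order),
radius grouping with a nearest-k cap (radii 0.4/0.8/global on the unit
sphere; empty groups fall back to the nearest neighbor), a shared per-point
MLP on (relative xyz ‖ attributes) with batch-norm + ReLU, and a max-pool
per group. After the global stage: fully connected → batch-norm → ReLU →
dropout 0.40 → linear to 2.

Both deep decoders emit one output per tick from the trailing 1 s window;
outputs with norm > 1 are rescaled onto the unit circle, smaller outputs
pass through (low confidence = slow movement). The first 1 s of a trial
emits zeros. The networks run on a small numpy layer library with manual
backpropagation (`cpbci.nn`); evaluation-mode forwards are deterministic
and training is bit-reproducible under a fixed seed.

## Training

Loss: `1 − cos(prediction, label)` — a differentiable surrogate whose
minimizer minimizes the average difference angle (ADA). Optimizer: Adam,
lr 1e-3, batch 64, up to 100 epochs with early stop after a 10-epoch ADA
plateau. The held-out split is the most recent 20% of windows by time
(honoring temporal structure); the epoch checkpoint with minimal held-out
ADA is returned — checkpoints capture batch-norm running statistics along
with the weights. Transfer learning pretrains one model on round-robin-
interleaved windows from several source subjects and fine-tunes on the new
subject (optionally freezing all but the head). Midsession recalibration
runs exactly 5 epochs at lr 3e-4 on the current session's first 4 runs and
keeps the final-epoch weights — deliberately no selection, since midsession
no validation data exists; a validation-selection variant sits behind a
config flag. The recalibration learning rate is larger than a cautious
fine-tune because only ~30 gradient steps are available.

A practical point discovered in closed-loop testing: a deep decoder trained
only on traditional-decoder runs suffers severe covariate shift when it
closes the loop itself (states the AR decoder rarely visited are exactly
where the network is untrained, and its errors become attractors). The
session protocol resolves this the same way the study design does: from the
second session on, the deep decoder controls some runs and its data
accumulates into later training sets. The CLI `simulate` command and the
acceptance experiments follow this protocol.

## Evaluation

- **NMSE** = mean over ticks of `|cursor − target|^2 / (2 * side^2)`. The
  squared-diagonal denominator is what makes the bounds exact: 0 when
  coincident, 1 at opposite corners. Multiply by 100 for "% screen size^2".
- **Axis correlation**: Pearson r per axis; constant trajectories give a
  missing value, never 0.
- **ADA**: mean angle in degrees between normalized predictions and unit
  labels; zero-norm predictions are excluded and counted. Uniform-random
  predictions give 90°.
- **Lag-scan**: NMSE of (cursor advanced by L) against the target, L on the
  tick grid up to 4 s; the argmin (ties → smallest lag) estimates the
  closed-loop delay. A pure-delay subject decoded by an intent oracle, with
  a cursor fast enough to track tightly (speed 0.5/s against the default
  target), recovers its reaction lag to within the transit residual
  (~0.1 s); at the default cursor speed the plant itself adds several
  hundred ms of catch-up lag on top — with the full default subject the
  measured closed-loop lags land in the 1.5–2.5 s range.
- **Chance level**: closed-loop runs in which the subject emits rest-state
  EEG regardless of the display (no intent); the decoder output is then
  driven by noise through the adaptive normalizer.

## Reduced problem sizes

The test suite and the acceptance experiments run on a 16-channel montage
subset at 250 Hz synthesis (decimation to 125 Hz preserved), 20–60 s trials
with 1–4 trials per run, the reduced network specs above, and 10–20 seeds
per Monte-Carlo claim. These sizes were chosen so the full suite runs on a
single CPU in minutes while leaving every qualitative contrast (decoder
ordering, training-data effect, lag recovery, negative controls) with a
comfortable margin.

Two further evaluation details matter in closed-loop data. First, label
marginals are anisotropic (decoder biases make some cursor→target
directions more frequent), so an information-free predictor that learns
only the marginal scores below 90° ADA; negative-control evaluations
therefore balance the evaluation labels over direction bins, which restores
the exact 90° chance anchor. Second, the gain from accumulating training
sessions saturates after a few hundred labeled windows for this stationary
subject: the 1→3-session improvement is large and reliable, while the
3→5-session improvement is of the same order as training/evaluation noise
per realization and is only visible in aggregate over seeds.

## Known limitations

- The subject never learns; effects that depend on co-adaptation (e.g. the
  traditional decoder's stability across sessions for humans) are outside
  the model.
- ADA floors well above 0° in closed-loop data because labels are
  instantaneous while the subject's intent is lagged; offline ADA is a
  noisy proxy of closed-loop NMSE, which is itself part of what the metric
  analysis demonstrates.
- The AR decoder uses only C3/C4 (no spatial filtering or neighbor
  channels), and the BCI2000-style normalizer is a reconstruction from its
  published behavior, not a port.
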