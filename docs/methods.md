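# Methods

## Model

`perceptime` treats subjective duration as the accumulated count of salient
changes in perceptual content, with no pacemaker of any kind. The pipeline
has four stages:

1. **Feature streams.** Each video frame is mapped to one activation vector
   per layer of a feature hierarchy. The canonical configuration reads an
   ImageNet-class convolutional classifier at four depths — conv2
   (290,400 units), pool5 (9,216), fc7 (4,096) and the 1000-way output
   probabilities — so lower layers react to edges and textures while higher
   layers react to object-level content. Any deterministic frame-to-vector
   map satisfies the extractor contract; the package ships a seeded
   hierarchical random-projection extractor (each layer a frozen Gaussian
   matrix applied to the previous layer, followed by a pointwise
   nonlinearity) and a pixel-identity extractor, so nothing in the test
   suite needs a pretrained network. Per layer, the signal passed on is the
   Euclidean distance between successive activation vectors, computed in
   double precision.
2. **Change detection.** Each layer k holds a threshold on that distance,
   updated per timestep as

       T[t+1]^k = T[t]^k − ((T_max^k − T_min^k)/τ^k) · exp(−D/τ^k)
                  + N(0, (T_max^k − T_min^k)/α)

   where D is the number of timesteps since the last reset. When the
   distance **exceeds** the current threshold, an event is recorded, the
   layer's accumulator increments, and the threshold resets to T_max^k with
   D = 0. Without noise the trajectory from a reset is a partial geometric
   sum converging to the closed-form floor
   `T_max − (T_max − T_min)/(τ·(1 − e^(−1/τ)))`, slightly below T_min
   (98.798 for conv2).
3. **Accumulation.** Per-layer event counts within a trial are the model's
   abstract units of subjective time; cumulative count-versus-time curves
   are retained for inspection.
4. **Calibration.** The per-layer counts of each trial form a feature
   vector mapped to seconds by epsilon-SVR under 10-fold cross-validation,
   trained on physical durations only. Human reports never enter fitting;
   they can be supplied solely as a reference series for RMSE scoring.

## Parameters

Per-layer threshold defaults (activation-distance units; τ and α are
dimensionless counts of 30 Hz timesteps):

| layer  | T_max | T_min | τ   | α  |
|--------|-------|-------|-----|----|
| conv2  | 340   | 100   | 100 | 50 |
| pool5  | 400   | 100   | 100 | 50 |
| fc7    | 355   | 100   | 100 | 50 |
| output | 0.55  | 0.15  | 100 | 50 |

The reference table for fc7 specifies only the ceiling explicitly; its τ
and α follow the values shared by every other layer, and this is flagged in
the config surface. Which tensor of the backbone "conv2" denotes is treated
as configurable: 290,400 matches the output of the *first* convolutional
stage of the canonical architecture, so layer identity is a `LayerSpec`,
not a hard-coded assumption.

Further knobs, with defaults and rationale:

- **Noise interpretation** — `N(0, s)` is read as Gaussian with **standard
  deviation** `s = (T_max − T_min)/α` (conv2: 4.8). The notation is
  ambiguous between SD and variance; SD is the default and
  `noise_interpretation="variance"` enables the other reading for
  sensitivity analysis. Note the noise enters the *threshold state*, so it
  accumulates between resets like a random walk; long quiet stretches can
  drift the threshold well below its noiseless floor, which is the model's
  main source of count variability.
- **Order of operations** — each timestep compares the distance against the
  *current* threshold first, then either resets (on an event) or applies
  one decay-plus-noise step. Ties do not trigger (strict `>`). The trial
  starts at the (attention-scaled) ceiling with D = 0, and a reset restores
  exactly T_max (no noise on the reset itself).
- **Clamping** — noise may transiently push the threshold outside
  [floor, T_max], including below zero; values are not clamped by default
  (`clamp_at_zero` exists but is off), since clamping would bias the
  random walk upward.
- **Attention** — `apply_attention_scaling(params, C)` multiplies T_min and
  T_max (hence also the noise scale and floor) by C > 0. Because
  everything scales, detection at attention C on distances d is *exactly*
  detection at C = 1 on distances d/C; event counts are therefore
  pointwise non-increasing in C.
- **Static variant** — `static_mode` freezes the threshold at the scaled
  T_max with no decay and no noise; its event count equals a direct
  per-timestep comparison, which the tests exploit as an oracle.
- **Calibration** — RBF kernel coefficient 1e-4, per-trial error penalty
  1e-3, insensitivity width ε = 0.1 (the common library default; the
  reference setting does not specify it), 10 folds, no feature
  standardisation (a switch exists). Negative raw predictions are kept and
  additionally clamped at 0 in a derived column.

### Penalty scaling with design size

The SVR penalty bounds each training trial's dual coefficient, so the
fitted function's total capacity is the *product* of the penalty and the
training-set size. The reference experiment used 4290 trials at penalty
1e-3. A desk-scale run with 260 trials and the same per-trial penalty has
~1/16 of that capacity and produces essentially flat estimates. The
harness's default `CalibrationSpec` therefore sets
`penalty_reference_n = 4290`: the effective per-sample penalty is
`1e-3 · 4290 / n_train`, which preserves the reference capacity at any
design size and reduces to exactly 1e-3 at the reference size. A bare
`CalibrationSpec()` leaves the penalty unscaled for users who want the
literal per-sample value.

### Rank correlation across folds

Out-of-fold predictions come from ten independently fitted regressors, and
an epsilon-SVR's intercept sits near the *median duration of its training
fold*. Pooling predictions across folds therefore mixes in an additive
per-fold offset that reflects which trials were held out — a nuisance, not
duration discrimination. `EstimateSet.rank_correlation()` computes the
Spearman correlation within each fold and averages across folds by
default; the pooled variant is available via `by_fold=False`.

### Attention sweep and calibration

`attention_sweep` learns the count-to-seconds mapping once, under normal
attention (C = 1), and applies those per-fold regressors to the counts
obtained at every other C (same streams, same detection noise, same fold
partition). This models an observer whose mapping from accumulated changes
to seconds was learned under normal conditions and is then probed under
altered attention. Re-fitting the regression at each C (`refit=True`)
instead lets calibration absorb most of the count shift, which erases the
very bias the sweep is meant to expose.

## Input regimes

- **Full frame**: a fixed centred patch (default 720×720 of a 1280×720
  source, 56 % of pixels); offsets are `floor((source − patch)/2)`.
- **Gaze**: a per-frame patch (default 400×400, ≈17 %) centred on the
  viewer's fixation. The window is **clamped** to lie inside the frame
  rather than zero-padded — padding would inject artificial high-contrast
  edges that inflate every change measure. Invalid gaze samples are
  forward-filled (leading invalids take the first valid sample); gaze
  sampled faster than the frame rate should be aligned to frames by
  nearest timestamp before use.
- **Shuffled gaze**: a seeded derangement (Sattolo's algorithm, a uniform
  random cyclic permutation — guaranteed fixed-point-free) reassigns each
  trial the gaze of a different trial; donor traces are truncated or
  extended by holding their final sample.

## Synthetic stimuli

The generator provides the study conditions at desk scale.

- **Trial design**: the 13 reference durations {1, 1.5, 2, 3, 4, 6, 8, 12,
  16, 24, 32, 48, 64} s; the reference design is 330 repetitions (4290
  trials), the desk default 20 repetitions (260 trials), which keeps a full
  pipeline run in seconds while preserving the design shape. Scene labels
  rotate across repetitions, so scenes stay balanced within durations.
- **Activation-change streams**: per trial and layer, distances are a
  Gaussian baseline (mean 0.6·T_min, SD 0.1·T_min of that layer) plus
  salient bursts of magnitude 1.25·T_max arriving as a Bernoulli process at
  the scene's `change_rate`; burst times are shared across layers, the way
  a real scene change perturbs the whole hierarchy at once. Expressing
  magnitudes in threshold units lets one scene spec drive every layer,
  including the probability-scale output layer. The three archetypes order
  change richness as city (1.2 Hz) > campus/outside (0.6 Hz) > office/cafe
  (0.3 Hz) — busy streets supply more varied perceptual content than a
  quiet room, which is the substance of the scene-bias phenomenon.
- **Videos**: bouncing bright squares over a mid-grey field; object count
  and speed come from the scene spec; per-object trajectories are retained
  so gaze can track them.
- **Gaze**: centre fixation, a reflected Gaussian random walk, or
  object-tracking.

All generators are pure functions of (parameters, seed).

**What this does and does not show.** The synthetic streams match the
statistics the thresholds care about (marginal magnitude, burst rate) but
not natural-video structure: no temporal autocorrelation beyond bursts, no
differential layer dynamics, no photometric realism, and synthetic gaze has
no saccade statistics. Passing tests therefore demonstrate that the
mechanism — thresholded accumulation plus calibration — produces the
qualitative phenomena (duration discrimination, central tendency, scene
bias, attention modulation) whenever its input has scene-dependent change
statistics; they do not certify behaviour on natural video, which requires
the real corpus, recorded gaze and a pretrained backbone.

## Reference configuration

With the original ~165-minute natural-video corpus at 30 Hz, recorded human
gaze, a pretrained AlexNet and the full 4290-trial design, this model
configuration has been reported to reach model-versus-human RMSEs of about
11.99 s (full frame), 10.71 s (gaze) and 11.79 s (shuffled), with
scene-bias deviations of roughly +24.4 % (city), −5.8 % (campus/outside)
and −9.0 % (office/cafe). None of those inputs ship with the package, so
desk-scale runs score RMSE against physical duration instead and reproduce
the *ordering* of the scene biases, not their magnitudes.

## Numerical and design choices

- Distances and thresholds in float64; the output layer's thresholds
  (0.15–0.55) would lose precision in float32 accumulation.
- Activation vectors are flattened in fixed C order (row, column, channel),
  so distances are bit-reproducible across runs.
- Each layer consumes an independent noise substream spawned from the trial
  seed; trials spawn independently from the run seed; the harness derives
  design/stimulus/detection/fold seeds from the config seed at fixed
  offsets. Same config, same seed ⇒ bitwise-identical results.
- Cross-validation sorts trials by `trial_id` before the fold split, making
  out-of-fold predictions invariant to input order and letting the
  attention sweep reproduce the baseline run row for row at C = 1.
- `KFold(shuffle=True)` with the derived fold seed; every trial appears in
  exactly one test fold and fold sizes differ by at most one.
- The normalised mean error averages the per-duration means with equal
  weight per duration level, not per trial.
- Scene-bias deviations are computed per duration level and then averaged
  (a pooled variant exists); trial-count-weighted deviations sum to zero
  within each level by construction.
- For non-canonical extractors (e.g. random projections on synthetic
  video), threshold floors are set per layer to a pooled distance quantile
  (default 0.6) with ceilings following the canonical T_max/T_min ratios —
  the canonical table is tuned to one specific backbone's activation
  scales and is meaningless on another's.

## Known limitations

- Event counts are non-decreasing under pointwise distance increases
  (noiseless) only on series shorter than about two decay times; on longer
  series an induced early event can, in contrived cases, push two late
  re-crossings past the end of the trial. The property test restricts
  itself to the guaranteed regime.
- Estimates near the short end can go slightly negative under RBF-SVR;
  both raw and zero-clamped columns are reported.
- The desk-scale study's biases are compressive to a degree set by the SVR
  capacity; magnitudes of scene deviations are not comparable to the
  reference configuration, only their order.
- The pretrained-backbone adapter is provided but untested in CI (it would
  require a network download); the extractor contract isolates it.
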