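# Methods

`laminar-decode` implements a layer-resolved visual-stimulus decoding
pipeline for trial-structured two-photon calcium (df/f) data: per-neuron
tuning and response-quality metrics, size-matched population decoding with
several multiclass classifiers, and depth/layer comparison statistics.
Because the real recordings it was designed around are large public
datasets, the package ships a synthetic laminar population generator with
the same statistical structure, and every analysis, test and acceptance
check runs end to end on that generator.

## Pipeline

1. **Trial averaging.** The df/f trace inside each stimulus presentation's
   half-open window `[start, end)` is averaged to a single amplitude,
   giving a response tensor indexed (neuron, condition, repeat).
2. **Normalization across neurons.** Each neuron's amplitudes are z-scored
   (ddof = 1) over all its (condition, repeat) entries; zero-variance
   neurons map to zeros. By default the z-score is fit on the full tensor
   before cross-validation — matching the preprocessing order of the
   standard recipe — with `normalize_on_train_only` available to refit on
   training folds and avoid that (mild, label-free) leakage.
3. **Spontaneous subtraction** (depth-series data): per-neuron mean
   subtraction only; no projection-based correction is attempted.
4. **Decoding.** Samples are single-trial population vectors; stratified
   5-fold CV with an 80/20 split (repeated stratified holdout when another
   test fraction is requested); accuracy is the fraction of correctly
   labeled test trials. To compare populations at matched size, a subset of
   `population_size` neurons is redrawn uniformly without replacement 15
   times (seed + repeat index) and fold accuracies are pooled; fold
   assignment is held fixed across selection repeats so repeats differ only
   in which neurons were drawn.
5. **Statistics.** Pairwise two-sided Wilcoxon rank-sum tests between
   layers (signed-rank for paired designs), with `*`/`**`/`***` codes at
   p ≤ 0.05 / 0.01 / 0.001; simple OLS of mean accuracy on a mean
   population property with R² and a two-sided slope p-value.

## Per-neuron metrics

With `R_c` the trial-mean response to condition `c` and the preferred
condition the argmax of `R_c` (ties to the lowest condition id):

- `OSI = (R_prefer − R_orthog) / (R_prefer + R_orthog)`, where `R_orthog`
  is the mean of the trial means at the two directions ±90° from preferred,
  at the preferred temporal frequency (one direction if only one exists on
  the grid). The ratio form is used, not circular variance.
- `DSI = (R_prefer − R_opposite) / (R_prefer + R_opposite)` with the
  +180° direction.
- `Reliability = 2/(T²−T) · Σ_{i<j} ρ(f_i, f_j)` — mean pairwise Pearson
  correlation of the T single-trial df/f traces at the preferred condition.
  This needs time-resolved traces; amplitude-only tensors give NaN.
- `SNR = (Σ_i R_i² − n·V) / (n·V)` over the n stimuli, where
  `V = mean_i(unbiased within-stimulus variance / repeats)` is the
  estimated variance of a trial-mean response. This reading of the noise
  term is chosen because it is the one under which a pure-noise neuron has
  SNR ≈ 0 in expectation (verified by Monte Carlo in the tests), so
  positive SNR means "responds above the noise baseline". SNR is *not*
  shift-invariant — the `R_i` enter squared — which the tests assert
  explicitly.

Degenerate inputs use sentinels rather than exceptions where a value can be
meaningfully propagated: zero OSI/DSI denominators → NaN; zero noise with
nonzero signal → +inf SNR; Pearson correlation of a zero-variance vector →
0 (also the tie convention inside the correlation decoder).

## Decoders

- **nn-corr** (authored here): class templates are element-wise means of the
  training population vectors; a test trial gets the class of the
  best-correlated template. Ties, within a 1e-12 tolerance, break to the
  lowest class id for determinism. Predictions are invariant to a common
  positive affine rescaling of all vectors (Pearson invariance).
- **svm-ecoc**: linear SVMs under an error-correcting output-code
  reduction. One uniform codebook scheme is used for every class count — a
  seeded random dense code with ~10·log₂(k) bits (scikit-learn's
  `OutputCodeClassifier`) — rather than switching schemes at small k;
  deterministic under the seed and standard practice.
- **knn** (k = 5), **decision-tree**, **naive-bayes** (Gaussian),
  **logistic** (lbfgs, max 1000 iterations): scikit-learn defaults
  otherwise; no hyperparameter tuning anywhere, since the protocol's point
  is comparing populations, not decoders.

Stratified fold assignment guarantees every class appears in training
folds. All randomness flows from explicit integer seeds; an experiment
rerun from its saved config is bit-identical.

## Synthetic generator

Grating tasks give neuron i a mixed orientation/direction von Mises tuning
curve

    μ_i(θ) = baseline + gain·[(1−m)·exp(κ(cos 2(θ−θ_i) − 1))
                              + m·exp(κ(cos(θ−θ_i) − 1))]

with preferred direction θ_i uniform on the circle (optionally snapped to
the stimulus grid for closed-form checks: with m = 1, no noise and zero
baseline, DSI = (1−e^(−2κ))/(1+e^(−2κ)) exactly). Image tasks use sparse
nonnegative per-image weights (Bernoulli(0.2) × Exp(1)). A trial amplitude
is μ plus Gaussian noise of per-layer `noise_sd` — trial noise is the one
variability knob, and reliability/SNR are *measured* outputs used for
validation, not inputs. Grating direction grids always use 360°/k spacing.

Trace emission renders each trial as amplitude × a fixed rise-and-decay
kernel normalized to unit mean (so window averaging recovers the amplitude
exactly) plus white noise at 30 Hz, with presentation order shuffled; the
amplitude stream is drawn identically with and without traces under the
same seed.

Defaults were fixed once as realistic for single-trial df/f amplitudes:
gain 0.3 df/f over a 0.05 baseline, κ = 1.5, direction mix 0.5, and trial
noise_sd 1.0 — noise several-fold larger than the tuned signal, consistent
with the low trial-to-trial reliability of real calcium data and with
decoding accuracy that grows with population size without saturating by a
few hundred neurons. Stimulus presets mirror the two protocols the package
emulates: 8 directions × {1, 2, 4, 8, 15} Hz gratings and 119 natural
images at ~75 repeats; 32 directions at 11.25° spacing (TF 2 Hz) and 32
images at 70–120 (default 90) repeats.

What the generator does **not** emulate: correlated (shared) trial-to-trial
noise across neurons, neuropil contamination and calcium-indicator
dynamics, running/eye-movement covariates, non-Gaussian amplitude
distributions, and layer differences in tuning *width*. Passing tests
therefore show that the pipeline's machinery behaves correctly under the
stated statistical model — independent Gaussian trial noise on tuned
means — not that any particular laminar result holds in real cortex. One
visible consequence: because measured OSI/DSI are inflated by trial noise,
noisier layers show *higher* apparent selectivity, an estimation bias the
depth-profile driver points out.

## Benchmark study designs (`laminar_decode.studies`)

- **L4 advantage**: four 100-neuron layers, 8 directions × 40 repeats,
  noise_sd {L2/3: 1.0, L4: 0.5, L5: 1.2, L6: 1.0} — L4's noise halved,
  L5 the noisiest, emulating the laminar accuracy ordering under study
  (L4 highest, L5 lowest). Decoding at matched size 64 with 15 selection
  repeats; pairwise rank-sum tests on pooled fold accuracies.
- **Depth series**: 11 planes at 70–420 μm; trial noise
  0.6 + 0.9·|depth − 245|/175, lowest mid-cortex, so stimulus SNR peaks in
  the middle planes; 32-direction task, 100 neurons per depth, 64-neuron
  decoding with 5 selection repeats; accuracy regressed on mean SNR.
- **Chance floor**: gain-0 (untuned) 64-neuron population, 32 classes × 20
  repeats; every decoder's pooled correct count is checked against the
  exact central 99% binomial interval around 1/32.
- **Size sweep**: one 300-neuron population, sizes {4, 8, …, 256}, 15
  selection repeats.

Problem sizes (repeats per condition, selection repeats for the depth
series, replicate counts) are desk-scale choices that keep a full replicate
set in tens of seconds while leaving every statistical property
well-resolved; the stimulus presets retain the full protocol scales.

## Numerical conventions

- Epoch windows are half-open, 0-based timepoints.
- Tie-breaks everywhere go to the lowest condition/class id.
- Rank-sum tests use the exact distribution for untied samples up to size
  25 per group, otherwise the normal approximation with tie/continuity
  correction; all-zero paired differences report p = 1 (ns) rather than
  erroring.
- No multiple-comparison correction by default (pairwise significance is
  reported raw, as is conventional for these layer comparisons); a Holm
  step-down flag is available.
- Depth→layer mapping: < 250 μm L2/3, 250–365 μm L4, 375–500 μm L5,
  ≥ 550 μm L6; the gaps (365, 375) and (500, 550) μm are unassigned and
  excluded from layer comparisons.
- A global experiment seed spawns per-stage seeds as
  `seed + 1000·stage_index (mod 2³¹−1)`.

## Known limitations

- The fold-level accuracies pooled across selection repeats are not fully
  independent (subsets overlap), so rank-sum p-values between layers are
  anti-conservative in absolute terms; they are used comparatively, as in
  the protocol this package implements.
- Normalizing before CV leaks (label-free) scale information; the
  train-only flag quantifies that this does not change any qualitative
  result on synthetic data.
- The generator's independent-noise assumption makes decoding easier than
  in real cortex at matched SNR (no shared noise to limit information).
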