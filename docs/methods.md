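# Methods

This note documents the models, numerical choices and synthetic-data design
behind `faceenc`, in the spirit of a package methods appendix: enough detail
to reimplement every stage, plus the reasoning behind the decisions that were
genuinely open.

## Signal chain

Raw multichannel signals (any linear unit, sampling rate ≥ 1 kHz so the
140 Hz band edge sits well below Nyquist; the synthetic default is 2048 Hz)
pass through:

1. **Notch filter** — IIR notch at the mains frequency (default 50 Hz),
   quality factor 30, fundamental only, applied zero-phase
   (forward–backward). The −3 dB width is ≈1.7 Hz; the passband ≥ 5 Hz away
   is attenuated < 1 dB.
2. **Common-average reference** — per-sample mean of the *good* channels
   subtracted from every channel. Channels flagged bad are excluded from the
   reference but still re-referenced. An optional amplitude flagger
   (`flag_bad_channels`) marks a channel bad when > 1 % of samples deviate
   from the channel median by > 8 robust SDs (1.4826 × MAD); it is a coarse
   stand-in for visual artifact screening and is off by default.
3. **HFB amplitude** — 110–140 Hz band-pass, 4th-order Butterworth applied
   forward–backward (the stated order is the design order; zero-phase
   filtering doubles the effective order but preserves envelope timing
   relative to the stimulus, which matters for lagged regression), then the
   modulus of the analytic signal from the Hilbert transform.
4. **Epoching** — one epoch per 30 s stimulus block, with 0.2 s of pre-onset
   samples retained solely for baseline statistics. The fifth music block is
   dropped by default (the stimulus shows no faces there). Intervals are
   half-open `[start, end)`; all times are seconds from recording start.
5. **Resampling to 400 Hz** — polyphase anti-aliased conversion
   (`resample_poly`). Two deliberate details: plain decimation is forbidden
   (the broadband envelope would alias), and the polyphase filter uses
   line-extrapolated padding, because zero padding puts a step transient at
   the epoch edge — i.e., inside the 80-sample baseline window — and the
   baseline SD estimate is very sensitive to it.
6. **Square root** — variance stabilization of the amplitude. Resampling
   ripple can produce tiny negative excursions near sharp transients; values
   above −10⁻⁶ of the scale are clipped to zero, anything more negative is
   treated as an upstream bug.
7. **Baseline z-score** — per block and channel, subtract the mean and
   divide by the SD of the −0.2–0 s pre-onset samples.

The chain is scale invariant (all operations before the z-score are linear
or monotone-power; the z-score removes affine scale), and channels are
processed independently after the reference step. Both properties are
tested.

## Features and design matrices

Per-frame emotion scores (48 named features in [0, 1], any frame rate,
optionally one row per detected face) are reduced per frame by the maximum
across faces, then bin-averaged into 0.5 s bins (2 Hz) within each block
using the same half-open window convention as the response bins, so feature
row *t* and response row *t* refer to the same stimulus time. Frames with no
face score zero for every feature (only the wholly face-free fifth music
block is excluded outright); empty bins inherit the previous bin's value,
with a logged warning. Bin-averaging rather than interpolation was chosen
because it matches the response binning exactly and is itself anti-aliasing.

The lagged design has one column per (feature, lag), feature-major, with
lags {0, 0.5, 1} s. Lag τ means the stimulus at *t − τ* predicts the
response at *t* — the causal direction. Rows whose lagged time precedes
block start are zero-padded (scores are non-negative activations; zero means
"absent"), and blocks never leak into each other. Features stay on their
native [0, 1] scale with no per-fit standardization: cross-subject weight
comparability is provided by the shared ridge penalty instead, and
standardizing would defeat that.

## Encoding model

Per subject × region × condition, contact responses are concatenated
row-wise with the design tiled once per contact — one weight vector per
region (contact averaging is available behind
`PipelineConfig.contact_aggregation = "average"`). The ridge solution is
computed on centered data, which is algebraically identical to leaving the
intercept out of the penalty; `alpha = 0` falls back to least squares. The
solver is verified against a direct solve of the regularized normal
equations with an explicit intercept column (worst observed relative error
~10⁻¹³ over random instances).

Cross-validation uses five *contiguous* temporal segments per contact,
aligned across contacts. Contiguous rather than random folds limit leakage
through temporal autocorrelation; the choice is configurable in principle
but contiguous is the package default and the only mode exercised. Per-fold
accuracy is the Pearson r between held-out measured and predicted responses;
the fit's accuracy is the mean of the five per-fold r values (not one r on
pooled predictions). A fold whose held-out response is constant yields NaN
and is excluded from the mean with a warning.

The shared penalty is selected by evaluating each candidate on every dataset
with the *same* fold partitions (variance reduction, determinism) and taking
the value maximizing the unweighted mean of cross-validated accuracy; ties
resolve to the smallest penalty. The search is SVD-accelerated: one SVD per
training fold serves all 20 grid values.

Weight summaries use per-fold weights averaged after taking absolute values
(mean over 3 lags × 5 folds per feature; `weight_reduction = "max"` is the
alternative). No refit on the full data is performed.

## Inference

**Temporal-shuffle test.** The null destroys the temporal alignment between
features and response while preserving everything else: all 48 feature
columns of the condition's 2 Hz matrix move together, the lagged design is
rebuilt (block boundaries respected), and the model is re-fitted at the
already-selected shared penalty with the same folds. The p-value is
two-tailed around the null median with add-one correction,
`p = (1 + #{|null − med| ≥ |obs − med|}) / (n_perm + 1)`, so `p` is never 0
and never below `1/(n_perm + 1)`. The shared penalty is *not* re-selected
inside permutations: it is a single global constant of the analysis, and
re-selection would multiply cost twenty-fold.

Two shuffle modes exist. Joint row permutation whitens the features'
autocorrelation while the response keeps its own; measured on AR(1)
responses (coefficient 0.3 at the 2 Hz bin rate) this is anticonservative —
empirical type-I error 0.095 at nominal 0.05 over 200 null datasets × 200
permutations. A random circular shift preserves the features'
autocorrelation and measures 0.035–0.075 across seeds, inside the binomial
95 % band. The package default is therefore `shuffle_mode = "circular"`;
`"permute"` remains available for comparison. One known limitation: a
circular shift of a 360-row condition admits only 359 distinct nulls, so at
`n_perm` ≫ 359 null values repeat; for the default `n_perm = 5000` the
p-value floor is effectively 1/360, which is ample for a 0.05 threshold.

**Parametric tests.** One-sample, paired and unpaired t-tests are standard
two-sided tests; the unpaired test uses the pooled (equal-variance)
convention, df = n₁ + n₂ − 2 (so groups of 8 and 13 report df = 19), and the
paired test df = n − 1. A zero-variance sample exactly at the hypothesized
mean returns t = 0, p = 1; zero variance elsewhere raises. The voice effect
is the per-subject difference Δr = r_speech − r_music, compared between
developmental groups with the unpaired test.

**Weight–age correlations.** Per-feature Pearson r (two-sided, uncorrected
p, as is conventional for this exploratory ranking; a Benjamini–Hochberg
helper is provided for users who want adjusted values) across the subjects
whose designated fit reached permutation significance (p < 0.05). Features
are ranked by r descending, ties broken by feature name — deterministic.
The complex group defaults to {guilt, embarrassment, pride, envy};
`include_interest_in_complex` adds "interest" for the five-emotion grouping.

## Synthetic data

The generator emulates the study conditions end to end:

- **Stimulus** — 13 interleaved 30 s blocks, music first (seven music, six
  speech), so speech and music each contribute six blocks after the
  face-free fifth music block (absolute block 9) is excluded; 360 rows per
  condition at 2 Hz.
- **Features** — per block, Gaussian noise smoothed over ~1.5 s (2 Hz lag-1
  autocorrelation ≈ 0.95, emulating the slow, smooth character of expression
  scores), plus sparse positive bursts (Poisson events, Hann-shaped,
  exponential amplitudes) mimicking expression episodes, squashed by a
  logistic into (0, 1). An expansion to per-face frames at any fps exists
  for testing the aggregation path.
- **Responses** — `y = Xw_true + ε` with AR(1) ε (coefficient 0.3 by
  default, so contiguous-fold CV is actually stressed), independent per
  contact; the noise variance is set per condition so feature-driven
  variance / noise variance equals the requested coupling SNR. Ground-truth
  weights are sparse: the ten group emotions carry amplitude spread over the
  three lags (profile 0.5/0.3/0.2) with random signs; other features are
  zero.
- **Cohorts** — `simulate_cohort` draws ages and sets complex-feature
  amplitudes to `base + slope·age + jitter` with basic amplitudes constant
  plus jitter. Noise variance is *constant across the cohort* (the SNR
  parameter refers to the subject at the median coupling). This is the
  physically sensible model — recording noise does not know coupling
  strength — and it matters statistically: scaling noise per subject would
  make weight-estimation error grow with age and leak an artifactual
  positive age correlation into every feature's |w|. The default cohort SNR
  of 2 keeps weight estimates reliable, mirroring the real analysis's
  restriction to significantly predicted subjects. `simulate_group_contrast`
  builds the two-group design (8 childhood / 13 post-childhood by default)
  with coupling only in a designated group.
- **Raw signals** — per channel, an independent in-band carrier normalized
  to unit mean analytic amplitude, multiplied by the target envelope, plus
  pink (1/f-amplitude) background noise and a channel-common 50 Hz line
  component. The carrier is a frequency-wandering constant-amplitude tone
  (wander confined to the flat mid-band, so filter-edge droop does not turn
  frequency wander into amplitude fluctuation) mixed with 5 % Gaussian band
  noise (`carrier_stability = 0.95`). A purely Gaussian carrier has a
  Rayleigh envelope whose fluctuations are as large as the envelope itself;
  with only ~6 independent envelope samples in a 0.2 s baseline, that makes
  the baseline z-score denominators so noisy that pooled envelope recovery
  is capped near r ≈ 0.65 regardless of coupling strength. The stabilized
  carrier keeps the imposed modulation, not the carrier's own stochasticity,
  dominant.
- **Subject-level raw generation** — the per-contact envelope is
  `(1 + m·u)²` with `u` the z-scored lagged predictor plus AR(1) noise at
  the requested SNR and `m = 0.3` the modulation depth; the square
  compensates the pipeline's square-root transform, so the normalized output
  is (up to extraction noise) linear in the ground-truth coupling. Outside
  the blocks the envelope rests at the contact's mean stimulus level. The
  raw-validation stimulus inserts 2 s inter-block pauses: with contiguous
  blocks, the −0.2–0 s baseline samples the *previous block's* modulated
  envelope, which injects order-1-z random offsets per block and is a
  genuine property of baseline z-scoring under continuous stimulation, not a
  generator artifact. The pauses isolate coupling recovery from that
  confound; the default cohort stimulus remains contiguous like the film.

What the generator does **not** emulate: real neural spectra beyond a 1/f
background, epileptiform artifacts, inter-contact correlation structure
beyond shared stimulus coupling, visual low-level covariates correlated with
the emotion features, or actual facial dynamics. Passing tests therefore
demonstrate that the pipeline recovers what it assumes — linear lagged
coupling under bounded smooth features and autocorrelated noise — not that
real cortex behaves this way.

## Problem sizes and runtimes

The test suite and the acceptance script size their simulations for a
single-CPU desktop run: solver and design-contract checks are instantaneous;
end-to-end raw recovery uses one 13-block subject with 4 region contacts at
2048 Hz (seconds); permutation calibration uses 200 null datasets × 200
shuffles with a single contact (about 1–2 minutes via the batched
Gram-update cross-validation path, which is verified exactly equivalent to
the per-fit path); the group contrast uses 8 + 13 subjects and the
weight–age cohort 12 subjects at the binned-response level (tens of
seconds). The binned level is the generative counterpart of the fitted
model, so cohort-scale claims are tested where the statistics live, while
the raw chain is validated separately on single subjects.

## Known limitations

- The EDF writer targets plain 16-bit EDF (1 s records, integer sampling
  rates); the BIDS reader handles the generic single-recording iEEG layout
  only.
- Baseline z-scoring with a 0.2 s window is intrinsically noisy (~6
  independent amplitude samples at a 30 Hz bandwidth); per-block offset and
  gain jitter from this source propagates into pooled accuracies on real
  data as it does on synthetic data with contiguous blocks.
- The circular-shift null assumes approximate stationarity of the feature
  process across the condition; with 360 bins it offers at most 359 distinct
  shifts.
- Fold structure is contiguous-only in practice; random folds would require
  an explicit leakage analysis under autocorrelation.
- The weight–age analysis inherits the usual caveat of absolute-value
  summaries: |w| estimates are upward-biased at low SNR, which is why
  inclusion filtering (or adequate SNR in simulation) matters.
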