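# Methods

`dyadsync` implements a dyadic (mother–child) neurophysiological synchrony
analysis: cardiac vagal coupling estimated from interbeat intervals, cortical
coupling estimated from hyperscanning fNIRS by wavelet transform coherence,
and moderation models asking whether either form of synchrony conditions the
relation between maternal affect and child emotion dysregulation.  Because no
public dataset with this structure exists, the package includes a first-class
synthetic cohort generator whose defaults reproduce the statistical scale of
such a study; all calibration and property checks run against it.

## Cardiac branch: continuous RSA and epoching

Respiratory sinus arrhythmia (RSA) is estimated from the interbeat-interval
(IBI) series as the natural log of the IBI variance (ms²) inside a 15-s
sliding window, emitted at 1 Hz.  Processing steps and their parameters:

* **Beat artifact correction.** An IBI deviating more than 30% from the
  running median of its 9 neighbours is corrected — short beats merged with
  their successor, long beats split into `round(ibi/median)` equal beats —
  conserving total elapsed time exactly.  A series with more than 20% flagged
  beats is marked unusable and its dyad excluded with a logged reason.  The
  30%/20% thresholds are design choices standing in for manual beat editing.
* **Uniform resampling.** Cubic interpolation of IBI against its ending beat
  time, sampled at 4 Hz before filtering.
* **Respiratory band-pass.** Zero-phase 4th-order Butterworth;
  0.12–0.40 Hz for adults and 0.24–1.04 Hz for young children (standard
  psychophysiology conventions; configurable).
* **Windowing.** The 15-s window is centred and half-open
  `[t − 7.5, t + 7.5)`, stepped at 1 s; the first/last half-windows are
  truncated rather than dropped so a 300-s task yields a full 300-sample
  series.  A variance floor of 1e-6 ms² keeps the log finite on silent input.
* **Epoching.** Consecutive non-overlapping blocks of 29 samples are
  averaged (≈30-s epochs; 10 per 300-s task); the trailing partial block is
  discarded.  The baseline reference is the mean of the last 29 baseline
  samples.  Whether those "last 29" are 1-Hz samples or epoch units is
  ambiguous in the source conventions; we take 1-Hz samples.

## RSA synchrony: baseline-referenced coupled autoregression

Per dyad, with child epochs C_t, mother epochs M_t and baseline references
C_base, M_base:

    C_t − C_base = a_i (C_{t−1} − C_base) + s_i (M_t − M_base) + ε_t

s_i (the concurrent mother→child slope) is the dyad's RSA synchrony.  This
preserves the three stated ingredients of the Bayesian SEM approach it
stands in for — baseline referencing, autoregression control, concurrent
cross-partner slope — in a transparent, reproducible estimator.  Two fitters:
per-dyad least squares, and an empirical-Bayes normal–normal model
(`hierarchical_map`) in which per-dyad OLS slopes are shrunk toward a group
mean μ_s under a prior scale τ_s estimated by marginal likelihood.  Shrinkage
never moves an estimate past the group mean.  Because the original lag
convention is not recoverable, a lag-1 mother term is available
(`mother_lag=1`); concurrent is the default.  Dyads with rank-deficient
designs (e.g. a constant partner series) are excluded and logged.

## fNIRS branch

Order is enforced (re-running a stage raises): intensity → optical density →
channel pruning → spline motion correction → wavelet motion correction →
modified Beer–Lambert → band-pass → downsample to 1 Hz → region aggregation.

* **Optical density**: OD = −ln(I/Ī) against each channel × wavelength
  temporal mean.  Note this referencing recovers concentration *changes* up
  to a per-channel constant; all downstream analyses are invariant to that
  constant.
* **Channel QC**: a channel fails if raw-intensity CV > 15% at either
  wavelength or more than 5% of samples are flat.  A region (left/right
  dlPFC, 4 channels each) is invalid with fewer than 2 usable channels; a
  dyad with any invalid region is excluded from neural analyses.  The
  thresholds follow common fNIRS practice; the source names the criteria but
  not the numbers.
* **Motion correction**: segments where the 1-s moving SD exceeds 5× its
  median are corrected.  Spike segments are replaced by a linear bridge
  between clean neighbours plus the spline-detrended residual; segments whose
  across-segment level jump exceeds 5× the clean first-difference SD are
  treated as step artifacts and the tail re-levelled.  A wavelet pass
  (db4, symmetric extension) then zeroes detail coefficients beyond
  1.5 × IQR outside the quartiles.
* **Beer–Lambert**: 760/850 nm extinction coefficients from the standard
  compiled table (cm⁻¹/M); differential pathlength factors from the general
  age × wavelength polynomial fit, so child and adult recordings use
  different effective pathlengths.  HbT ≡ HbO + HbR by construction.
* **Filtering/downsampling**: 0.01–0.5 Hz zero-phase band-pass (deliberately
  wide — the coherence FOI does the narrow selection), then low-pass at
  0.4 × target and interpolation onto the exact 1-Hz grid (7.81→1 Hz is a
  non-integer ratio).

## Wavelet transform coherence

The Morlet CWT (ω₀ = 6, 12 voices per octave, geometric scale grid,
FFT-based with zero padding) feeds the squared coherence

    r²(t,s) = |S(W_xy/s)|² / ( S(|W_x|²/s) · S(|W_y|²/s) )

with the standard smoothing S: a Gaussian in time with std equal to the
scale (applied via its analytic transfer function) followed by a boxcar of
0.6 octave across scales.  Without smoothing coherence is identically 1, so
an unsmoothed request is refused.  Series are linearly detrended and
variance-normalised first; coherence is scale-free, but detrending
stabilises edge behaviour.  The cone of influence is the e-folding boundary
√2·s.  The frequency band of interest 0.02–0.1 Hz (periods 10–50 s) is
averaged over task time to one scalar per dyad × region × chromophore.
Points under the COI are excluded by default — at 50-s periods in a 300-s
task the contamination is material — with `coi_policy="include"` available
to reproduce the convention of tools that keep them.  Coherence is symmetric
by definition and the implementation canonicalises argument order so
coherence(x, y) and coherence(y, x) are bit-identical.

For permutation analyses each signal's transform and smoothed auto-spectrum
are cached (`CwtCache`), so an n×n pairing grid costs O(n) transforms plus
one cross-smoothing per pair.

## Moderation models and Johnson–Neyman probing

Ten OLS models (2 affect scales × {RSA synchrony, left/right dlPFC coherence
in HbO/HbR}): outcome child dysregulation; focal predictor and moderator
grand-mean-centred before forming their product; covariates the opposite
affect scale, child gender, income (ordinal integer).  Standardised betas
use analysed-sample SDs after listwise deletion.  With 6 predictors the
model F has (6, n−7) degrees of freedom.  No multiple-testing correction is
applied across the ten models, matching the design this mirrors;
Benjamini–Hochberg is available as an option.

Johnson–Neyman boundaries solve θ(m)² = t²crit·Var(θ(m)) for the simple
slope θ(m) = B_iv + B_int·m, a quadratic whose real roots partition the
moderator axis; regions are labelled by the sign and significance of θ at
their midpoints, and roots outside the observed moderator range are flagged.
The closed form is verified against a brute-force 1e-4-grid scan of simple
slope t-tests in the test suite.

## Random-pairing permutation control

Each mother is re-paired with a random child from another dyad — a uniformly
sampled derangement, so each child appears exactly once per permutation and
no mother keeps her own child (100 permutations by default).  FOI coherence
is computed for each pseudo-pair and averaged per mother; the moderation
models are refit with the pseudo values.  On coupled cohorts true-pair
coherence exceeds pseudo-pair coherence, and interactions driven by true
coupling vanish under re-pairing.  Derangements were chosen over
independent per-mother sampling to hold each child's appearance count fixed;
the alternative wording ("a random child from another dyad") would also
admit independent sampling, which can be emulated with repeated size-1
schemes if desired.

## Synthetic cohort generator

The generator is the package's study-condition definition, not a test prop.

* **Heartbeats.**  IBI(t) = mean + A·e(t)·sin(2πf t) + jitter, with mother
  f = 0.25 Hz / A = 60 ms around 800 ms and child f = 0.5 Hz / A = 40 ms
  around 600 ms.  The log-envelope log e(t) is a band-limited (0.01–0.05 Hz)
  Gaussian process with SD 0.5; the child's log-envelope regresses on the
  mother's with slope equal to the per-dyad coupling s_i
  (drawn N(−0.01, 0.03²) by default, the observed synchrony scale), plus an
  independent component scaled by 0.1·√(1−s²).  Because RSA is a windowed
  log-variance, child-on-mother epoch regression recovers s_i by
  construction.  The envelope SD, partner fraction and 2-ms beat jitter were
  fixed by decomposing the slope-estimate error budget so that a 10-epoch
  within-dyad regression resolves couplings at the observed scale; with
  them, the median Spearman correlation between generating and estimated
  couplings is ≈0.55 at s_i ~ N(0.2, 0.05²) (n = 80).  Amplitudes must keep
  IBI > 200 ms or generation refuses.
* **Hemodynamics.**  Region-level HbO mixes a shared band-limited
  (0.02–0.1 Hz) source with weight √f_i and an independent source with
  weight √(1−f_i), where f_i ~ N(0.25, 0.15²) clipped to [0,1] is the
  per-dyad shared fraction (the generating coherence truth); HbR is −0.3 ×
  HbO plus a noise term.  Channels add Mayer-wave (0.1 Hz), respiratory
  (0.25/0.5 Hz), cardiac (1 Hz) sinusoids and white noise at µM-scale
  amplitudes chosen so measured FOI coherence of uncoupled pairs sits near
  the independent-signal baseline (≈0.35 for 300 samples) and coherence
  rises monotonically with f_i.  Intensities come from the forward
  Beer–Lambert model with the same extinction table the analysis inverts, so
  the conversion round-trips exactly.  Optional motion artifacts (spikes ≥5×
  signal SD lasting 0.5–2 s, and baseline steps) arrive at Poisson times.
* **Behavior.**  PA ~ N(36.21, 6.78²), NA ~ N(19.54, 7.26²), gender
  Bernoulli(0.54), income in 4 ordered brackets with observed proportions.
  Dysregulation follows the linear moderation equation on deviations from
  the generating means, with default coefficients at the observed-cohort
  scale (intercept 1.79, interaction −0.47 per PA-point × synchrony-unit,
  residual SD 0.30 giving outcome SD ≈0.37).  The synchrony entering the
  equation can be the cardiac coupling (default) or the neural shared
  fraction (`sync_source="coherence"`).
* **Seeding.**  One global seed spawns a substream per dyad, so cohorts are
  bit-reproducible and extensible: growing a cohort appends dyads without
  changing existing ones.

What the generator does *not* emulate: real ECG waveforms and R-peak
detection, scalp/skull optics and partial-volume effects, pulse-wave
dynamics, serial dependence in questionnaire responses, or missingness
mechanisms.  Passing tests therefore demonstrate the pipeline's arithmetic,
calibration and discriminative behaviour under the assumed data-generating
structure, not robustness to everything real recordings can contain.

## Problem sizes used by the test and acceptance runs

Simulation-based checks run at sizes chosen as the package's own defaults:
type-I error of the interaction test over 1000 behavioural cohorts of 80
dyads; median interaction bias over 500 cohorts; Johnson–Neyman oracle
agreement over 100 random fitted models; true-vs-pseudo coherence over 200
seeds of 4-dyad cohorts; pseudo-moderation null behaviour over 100 cohorts
of 20 dyads with 20 permutations each (the region-level signal model is used
directly there, since the optics round trip is exercised separately).

## Numerical choices and degenerate inputs

Variance floor 1e-6 ms² (RSA); coherence clipped to [0,1] against
floating-point overshoot; degenerate J-N quadratics (zero interaction
variance) return a single global region; zero-variance variables yield blank
correlation entries; constant-partner dyads are excluded from coupling fits
rather than fitted; channels flagged in their entirety by motion detection
are marked unusable rather than corrected.

## Known limitations

The coupling estimator is a deliberate simplification of a Bayesian SEM; it
matches that model's stated structure but not its priors or posterior
summaries, and per-dyad estimates at 10 epochs are noisy (the hierarchical
fitter is provided for exactly that reason).  The spline motion correction
flattens genuine slow signal inside flagged segments.  Wavelet coherence at
periods near the task length is COI-dominated no matter the policy.  The
J-N procedure treats the fitted covariance as known (no simple-slope
bootstrap).
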