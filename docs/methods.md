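# Methods

This note documents the models, numerical choices and limitations of
`pupilbci` at the level a maintainer or reviewer needs. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal chain

### EEG preprocessing (`pupilbci.preprocess`)

Raw EEG is processed as a continuous block, in this order:

1. **Resampling** to 128 Hz (polyphase, anti-aliased, line-extension
   padding so a DC signal survives the edges). Rational rate ratios are
   approximated by `Fraction(...).limit_denominator(1000)`, never silently
   truncated.
2. **Common average reference.** Subtracting the instantaneous channel
   mean puts the data in the zero-channel-mean subspace: rank ≤ N−1. This
   deliberate rank deficiency is repaired downstream (see CSP
   regularization), not here.
3. **Band-pass 8–30 Hz**, windowed-sinc (Hamming) FIR applied
   forward–backward (`filtfilt`): zero net group delay, attenuation
   doubled. The filter order follows the Hamming design rule
   numtaps ≈ 3.3·rate/transition with a 2 Hz transition width (default
   211 taps at 128 Hz, forced odd). The source material names only the
   filter class ("zero-phase forward/backward FIR"); the order and window
   are this package's reproducible choice, recorded in `PreprocConfig`.
   Segments shorter than 3 filter lengths are rejected rather than
   filtered — filter blocks, then epoch.

Epoching windows are half-open `[start, end)` in seconds relative to the
go cue. The EEG feature window defaults to [0.5, 6.0) s — mirroring the
pupil active window, since the original analysis does not state the EEG
epoch bounds — giving T = 704 samples at 128 Hz. No artifact rejection is
performed anywhere, by design: the method is meant to survive uncurated
data.

### CSP (`pupilbci.csp`)

Estimation follows the classical two-class recipe: per-trial
trace-normalized covariances, class means, composite eigendecomposition,
whitening, simultaneous diagonalization, W = B′P. Numerical choices:

- **Whitening exponent.** The printed formula P = λ_c^{−1}U_c′ does not
  satisfy PC_cP′ = I; the inverse *square root* λ_c^{−1/2} does, and is
  what is implemented (and asserted to 1e−8 in tests).
- **Orientation of W.** With Z = WE and E channels×samples, W must be
  filters×channels, i.e. W = B′P; rows of W are filters, columns of the
  pseudo-inverse are patterns (scalp topographies).
- **Regularization.** Each class covariance is shrunk by
  ε·trace/N·I (ε = 1e−6 default). Whitened dimensions whose composite
  eigenvalue sits at the shrinkage floor (≤ 10× the floor, or below
  1e−9×max) are discarded — the CAR null space lands exactly at the floor,
  so this removes it without touching the discriminative subspace. If
  fewer than 2m usable dimensions remain, a `RankDeficiencyError` reports
  the deficient count.
- **Determinism.** Eigenvalues are sorted descending with a stable sort
  (ties keep original index order); eigenvector signs are fixed by making
  each vector's largest-magnitude component positive.
- **Features.** f_p = log(var_p / Σ_q var_q) over the 2m selected
  projections. The log-ratio is scale-invariant and is the field-standard
  companion to LDA; the source material says only "variances … are used",
  so a raw-variance switch (`log_variance=False`) is kept. Zero-variance
  projections are floored at ε_var·Σvar (ε_var = 1e−15) before the log.

### Pupillometry (`pupilbci.pupil`)

- **Gap policy.** Blinks and tracking losses are NaN-masked. Per sample
  the valid eyes are averaged (single-eye fallback); gaps ≤ 0.5 s in the
  averaged series are linearly interpolated; trials with < 75 % valid
  samples are flagged unusable (excluded and counted, never filled). The
  original analysis is silent on blink handling; these defaults are a
  deterministic, configurable rule chosen for reproducibility.
- **Baselining** is subtractive: the mean over [−2, 0) s before the cue is
  subtracted from the whole epoch. Subtractive (not divisive) matches the
  ~mm-scale, near-zero class averages of the published statistics.
- **Statistics** are computed over the active window [0.5, 6.0) s:
  mean, derivative (mean first difference × rate, mm/s — the source does
  not define its "derivative", this is the simplest consistent reading),
  max, min, range, population variance, and standardized third/fourth
  moments. Kurtosis is **non-excess** (Pearson; Gaussian → 3), because
  the published class averages straddle 3. A series with exactly zero
  range reports NaN moments rather than numbers.
- **Spectrum.** Single full-trial segment, Hann taper, coefficients
  scaled by 1/n (×2 off-DC, Nyquist excluded) and compensated for the
  taper's coherent gain, so an on-bin sinusoid of amplitude a reads ≈ a.
  The series is demeaned before tapering — otherwise the window leaks the
  DC offset into the lowest bins — and the mean is reported as the DC
  amplitude directly. The band amplitude is the mean over 0 < f ≤ 0.2 Hz
  (the published table's band label; 0.3 Hz is selectable per the
  accompanying text, a discrepancy in the source).
- **Threshold rule.** The single-statistic classifier calls imagery when
  the trial statistic is *strictly* above the midpoint of the two class
  averages; the boundary itself is rest — a switch should not fire on
  ambiguity. The published trial-range threshold (0.471) is not the
  midpoint of its printed class means (0.474); the midpoint rule as stated
  is implemented.

### Classification (`pupilbci.classify`)

Fusion appends the baselined pupil mean (mm, unstandardized — its natural
scale *is* the task-evoked response) as the last element of the CSP
vector: 6 + 1 = 7 features at m = 3. Unusable pupil trials are imputed
with 0.0 (baseline-neutral) and flagged.

The LDA is scikit-learn's (solver `lsqr`) behind this package's surface,
with equal priors hardcoded by default (the trial design is balanced) and
the bias recomputed from the class means so the boundary sits *exactly* at
the midpoint of the projected class means (robust to solver round-off; a
feature vector at the midpoint scores 0.0 and is classified as rest).
Plain LDA refuses singular pooled covariances with a pointer to the
`shrinkage` parameter; shrinkage (including Ledoit–Wolf `"auto"`) blends
toward the diagonal and is recommended for 25-trial blocks, but defaults
to off.

## Evaluation (`pupilbci.evaluate`)

- **Protocols.** Within-block stratified 10-fold CV (seeded shuffling; the
  fold construction is unspecified in the source, stratification is this
  package's choice) with the *entire* pipeline — CSP, LDA, pupil
  threshold — refit per fold; and cross-block transfer with leakage guards
  (shared trial objects or shared block ids raise). Per-subject accuracy
  averages CV over blocks, or both transfer directions.
- **ITR.** bits/min multiplies bits/trial by 10, from the 6 s active trial
  duration (this reproduces the published trial↔minute ratio); the 12 s
  inter-trial spacing is deliberately not used. Configurable.
- **Kappa.** P₀ = 1/n_classes, not estimated marginals, matching the
  balanced design. (The published kappa table prints negative values that
  are inconsistent in sign, but not magnitude, with its own accuracies and
  definition; the definition is implemented as printed.)
- **Mutual information.** 2-D histogram plug-in estimate in bits; bin
  count per axis from the Freedman–Diaconis rule on each variable, the
  maximum shared by both axes; integer override available. Permutation
  z = (MI_obs − mean_perm)/sd_perm over 200 pairing shuffles with fixed
  bin edges. MI(x, x) = H(x) holds exactly for any binning (identical
  edges ⇒ diagonal joint histogram). **Binning and bias:** the plug-in
  estimator's independence bias grows as ≈ (B−1)²/(2N ln 2); FD applied to
  10⁴ continuous samples yields B ≈ 60 and a ~0.2-bit bias, while the
  10-bin configuration used in the original analysis keeps it below
  0.01 bits. Near-zero MI values are therefore only meaningful at modest
  bin counts, or via the permutation z, which is calibrated at any B.
- **Subgroups.** Split at the lower quartile of EEG-only accuracy
  (potential BCI illiterates); paired t, df = n−1, Cohen's
  d = mean(diff)/sd(diff) within each subgroup; zero-variance differences
  are flagged degenerate instead of producing a t statistic.

## Synthetic data (`pupilbci.synth`)

What it emulates: the block design (25 trials/5 min, 12 s apart, 6 s
active window, balanced randomized classes, stop cues); mu (10 Hz) and
beta (22 Hz) rhythms as *narrowband Gaussian processes* — not pure tones,
which would make trial covariances degenerate rank-1 — mixed over the
montage with a smooth topography centred on C4 (contralateral to the
imagined left hand), their power multiplied by 1 − erd_depth during
imagery with ~0.25 s softened edges; 1/f background sources at random
scalp locations; white sensor noise; and a pupil channel with baseline,
random-walk drift, per-eye measurement noise, blink gaps, and a sigmoid
dilation (plateau ~1.5 s post-cue, exponential decay in the break) with
trial amplitude ~ N(0.16, 0.05) mm on imagery trials only — the effect
scale mirroring the published class-mean gap (0.131 vs −0.030 mm).

Default amplitudes (µV at the peak channel): mu 5, beta 3, background 8,
sensor noise 4. The pupil drift step sd of 0.01 mm/sample is the
calibration constant: it makes the trial-mean noise sd ≈ 0.11 mm, placing
pupil-only threshold accuracy in the 65–85 % band at the default effect
size (bracketing the published 73.3 ± 8.1 %). It was chosen analytically
from the random-walk increment variance between the baseline and active
windows and is recorded in `SynthConfig`, not hidden.

Cohorts draw per-subject erd_depth (25 % "illiterate" subjects at
erd ≤ 0.08; the rest ~ N(0.5, 0.15) clipped) and pupil effect
(~ N(0.16, 0.05), independent of ERD — which is precisely what lets
fusion rescue low-EEG subjects), and plant an inter-block covariance
shift by jittering source topographies in block 2, reproducing the
within-block > cross-block accuracy ordering.

What it does **not** emulate: volume conduction from a real head model
(lead fields), EOG/EMG artifacts, light-driven pupil dynamics, gaze
dependence of pupil estimates, or non-stationarity within a block.
Passing synthetic-recovery tests therefore demonstrates the pipeline's
correctness and sensitivity under the assumed statistical structure, not
performance on real recordings.

## Experiment sizes in the test suite

The simulation-based checks use sizes chosen to keep estimates stable at
desk scale: null calibration averages 10 seeded 25-trial blocks; ERD
recovery uses one 200-trial block (100 per class) at erd_depth 0.6; the
degraded-SNR fusion comparison uses erd_depth 0.25 with 10 µV sensor
noise (2.5× default) and 50-trial blocks over 10 seeds. The degraded
regime intentionally keeps EEG-only accuracy above chance: at the chance
floor, "fused beats EEG" would be a coin flip and the comparison
meaningless.

## Known limitations

- The native container is HDF5 only; XDF import is out of scope (the
  on-disk dialect adds no testable computation).
- Only two classes; no multi-class CSP or shrinkage-CSP variants beyond
  the ε default.
- The histogram MI estimator is biased at large bin counts (see above);
  no k-NN or adaptive-binning estimator is provided.
- The pupil "derivative" statistic reduces to the epoch's endpoint slope;
  with the published definition unavailable, other readings (e.g. robust
  slopes) would change that row's values.
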