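# Methods

`mibci` re-implements, as a tested and reusable library, the offline analysis
chain of a cue-based left/right-hand motor-imagery BCI experiment: synthetic
sensorimotor-rhythm EEG generation, signal conditioning, common-spatial-pattern
(CSP) feature extraction, bootstrap SVM evaluation (per subject, pooled across
subjects, per distance level, and as window-length / time-from-cue sweeps),
the forearm-EMG mean-absolute-value chain, and the normality-gated paired
comparison used to contrast conditions.

## Synthetic sensorimotor-rhythm sessions

Because no recordings are distributed with the protocol this package models,
every analysis is driven by a generator that reproduces the statistical
structure the analysis assumes, with known ground truth.

**Protocol structure.** One session is a continuous 11-channel recording
(Fp1, Fpz, Fp2, F3, F4, Fz, Fc1, Fc2, C3, C4, Cz; 125 Hz) containing 15 left-
and 15 right-hand cues in randomized order. Each trial is a 10-s imagery cue
followed by 5 s of rest. The distance level cycles 1, 2, 3 within each class,
giving 5 trials per level per class — so a 10-subject cohort pools to 300
trials, 100 per level.

**Signal model.** The background is spatially mixed 1/f noise: one
power-law source per channel (PSD slope `-noise_exponent`, default 1),
mixed through a fixed near-orthonormal matrix drawn once per seed. This
gives realistic inter-channel correlation without a forward head model.
Two band-limited oscillator sources sit at C3 and C4, each the sum of a mu
(10 +/- 1 Hz) and a beta (20 +/- 1 Hz) narrowband-noise component, projecting
to neighbouring electrodes with a fixed falloff (Cz 0.35, Fc1/Fc2 0.30,
F3/F4 0.20). Event-related desynchronization is multiplicative: during a
cue the source contralateral to the imagined hand is scaled by
`1 - erd_depth`, starting `erd_onset` seconds after the cue. Optional
high-amplitude artifact bursts (Poisson, `artifact_rate`/min, 0.5 s,
Hann-windowed broadband noise) emulate movement artifacts.

**Defaults and what they mean.** Units are microvolts throughout.
`noise_scale=8` (per-source RMS), `mu_amp=1.5`, `beta_amp=0.8`,
`erd_depth=0.5`. No published characterization of the target population's
SNR or ERD magnitude exists, so these were chosen once to place the default
condition in the accuracy regime typical of novice motor-imagery users
(roughly 75–80% per-subject bootstrap accuracy with the full 10-s window)
and left fixed. `erd_depth` is the experimenter's dial for class
separability: 0 removes all class information, 0.8 with `noise_scale=2`
gives a near-ceiling subject.

**What the generator does not emulate.** No volume-conduction head model, no
eye/muscle physiological artifacts with realistic spectra, no non-stationary
ERD dynamics within the cue (the suppression is a step), no inter-subject
montage or rhythm-frequency variability (subjects differ only by seed: new
mixing matrix, noise, and trial order). Passing tests therefore show the
pipeline recovers the statistical structure it assumes — not that it would
reach any particular accuracy on real recordings.

## Conditioning chain

The continuous signal is band-pass filtered (4th-order Butterworth, applied
forward-backward so cue-locked windows suffer no group delay), then
per-channel mean-centred. The conventional 4–70 Hz analysis band is
unrealizable at 125 Hz; the pipeline helper clips the upper edge to
0.95 x Nyquist (59.4 Hz) and logs a warning, while the low-level
`bandpass_eeg` refuses edges at or beyond Nyquist outright. Alpha (7–13 Hz)
and beta (13–30 Hz) band powers — descriptive QC only, the classifier uses
CSP features exclusively — are Welch estimates on 1-s Hann segments with 50%
overlap, integrated over the band.

**Artifact subspace reconstruction.** Calibration on a segment regarded as
clean (>= one window; >= 30 s recommended) computes the covariance
eigenbasis and, over 50%-overlapping 0.5-s windows, the per-component RMS
mean and SD; the rejection threshold is mean + k·SD with k=20. Cleaning
processes consecutive non-overlapping 0.5-s windows: components exceeding
their threshold in a window are removed and the window reconstructed from
the retained subspace. Rectangular non-overlapping windows were chosen over
windowed overlap-add deliberately: windows with no flagged component pass
through bit-identical, so clean data is untouched, cleaning is idempotent,
and an infinite cutoff is exactly the identity. The cost is a possible
small discontinuity at window edges when a component is removed — acceptable
for burst artifacts an order of magnitude above background.

**Epoching.** Cue-locked windows `[cue + offset, cue + offset + length)` on a
0-based half-open sample grid, offsets and lengths rounded to the nearest
sample; labels (class, level, subject, session) travel with the trials.

## CSP

Per-trial covariances are trace-normalized (removing trial-amplitude
confounds) and averaged within class; a ridge of 1e-6 x trace/N keeps
short-window 11-channel estimates invertible. Filters solve the generalized
eigenproblem S_left v = lambda (S_left + S_right) v. Eigenvalues lie in
[0, 1] and equal each filter's variance ratio
w S_left w' / (w S_left w' + w S_right w'); the filter matrix W keeps the
J = 3 largest- and 3 smallest-eigenvalue eigenvectors (L = 2J = 6 filters)
and satisfies W (S_left + S_right) W' = I by construction. Spatial patterns
are the paired mixing columns A = (S_left + S_right) W'. Signs are fixed so
each filter's largest-magnitude coefficient is positive; equal eigenvalues
keep input order. Features are the canonical log-normalized variances
log(var_j / sum_k var_k) of the six filtered signals — scale-invariant by
construction. Per-filter "activity" (the across-trial mean variance of each
filtered signal, grouped by class/session) summarizes how strongly each
filter separates the classes.

## Evaluation protocols

Each bootstrap repetition refits everything — class covariances, CSP, feature
standardization, SVM — on that repetition's training trials only; held-out
trials never influence any fitted quantity.

- **Per subject:** 200 random stratified 20/10 splits of the subject's 30
  trials (10 train / 5 test per class; stratification avoids degenerate
  single-class training sets at n=30).
- **Pooled ("global"):** 70/30 splits of all pooled trials, stratified by
  subject x class. Stratifying by class alone lets per-subject class
  imbalances into each split; combined with subject-identifiable spatial
  structure this measurably biases the pooled null accuracy below chance
  (~46% vs ~50% with subject x class strata, 10 null subjects, 200 reps).
- **Per level:** the pooled protocol restricted to one distance level
  (100 trials per level in the 10-subject design).
- **Sweeps:** window lengths 1–10 s from cue onset, and 0–5 s offsets at a
  fixed 5-s window. The per-subject seed is derived independently of the
  axis value, so the full-length sweep point reproduces a direct
  `bootstrap_subject` call exactly.

**Classifier.** Linear-kernel SVM on features standardized with training-set
statistics (CSP log-variance features have magnitude ~log(1/2J) and tiny
class contrasts; without scaling a C=1 SVM grossly underfits). The
regularization strength is left at the library default C=1. An inner
stratified 5-fold CV over a log-spaced C grid is available
(`optimize_c=True`) but off by default: on 20-trial training sets the
selection is essentially noise, and the winner's curse of picking the C that
best fits a finite training sample measurably depresses null-data test
accuracy below chance (47.2% vs 49.1%, 12 null subjects x 80 reps). A
calibrated evaluation protocol takes the unbiased default.

**Seeds.** Every repetition's RNG is `default_rng([seed, rep])`; sweeps and
cohort generation derive sub-seeds through `SeedSequence`. Identical seeds
give bit-identical results end to end.

**Small-sample caveat.** Even with these choices, a single 30-trial subject's
null bootstrap mean has a 4–7% SD (train and test subsets of a fixed small
sample are anti-correlated), and a 10-subject pooled cohort's null mean
still carries ~2% cohort-level spread. Calibration checks therefore average
over cohorts; single-subject accuracies should be read with that spread in
mind.

## EMG chain

Both forearm recordings (8 channels, 200 Hz) are band-pass filtered
(10–500 Hz requested; the upper edge is clipped to 0.95 x Nyquist = 95 Hz
with a warning, since 500 Hz is unrealizable at 200 Hz) and full-wave
rectified. MAV is the mean of the rectified samples across channels and time
per armband, then averaged across arms. MAV is scale-equivariant and
additive over equal-length segments; on Gaussian noise of SD sigma it
estimates sigma*sqrt(2/pi), and on a unit sine 2/pi.

## Paired comparison

`compare_paired` applies Shapiro–Wilk to the paired differences — the
quantity whose normality the paired t-test actually assumes. If normality is
not rejected at alpha=0.05 the route is the two-sided paired t-test,
otherwise the two-sided Wilcoxon signed-rank test (exact null distribution
for n <= 25, normal approximation above). All-zero differences are reported
as degenerate with no statistic. Type-I calibration under i.i.d. normal
pairs is verified at 2000 simulated datasets. No multiple-testing
correction is applied.

## Problem sizes

Cohorts of 10 simulated subjects (300 pooled trials) for the null and level
analyses, 3 subjects for the signal-recovery and sweep analyses; 100–200
bootstrap repetitions for point estimates and 50 for the sweeps and
monotonicity checks. These sizes keep the full verification suite and the
reproduction script each within a few minutes on one CPU while leaving the
binomial/bootstrap noise well inside the margins the checks assert.

## Known limitations

- The ASR implementation targets burst artifacts; it does not implement the
  calibration-data auto-selection or Riemannian refinements of mature
  online implementations.
- EDF output is 16-bit with per-channel physical ranges from the data;
  markers travel in a JSON sidecar rather than EDF+ annotations.
- The simulator's homogeneous cohort (identical rhythm topography across
  subjects) makes pooled classification easier than reality; global-protocol
  accuracies on synthetic cohorts should not be compared to human studies.
- Multiclass CSP, regularized variants beyond the ridge, and Riemannian
  alternatives are out of scope.
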