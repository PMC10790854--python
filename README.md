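# mibci

Offline analysis pipeline for cue-based left/right-hand **motor-imagery
brain–computer interfaces**, driven by a synthetic sensorimotor-rhythm EEG
generator. It is aimed at BCI researchers who want a fully reproducible,
ground-truth-controlled testbed for the classic CSP + SVM decoding chain and
its evaluation machinery.

During imagined hand movement, the mu (~10 Hz) and beta (~20 Hz) rhythms
over the contralateral motor cortex desynchronize (ERD). Common spatial
patterns (CSP) exploit this: given class covariance matrices Σ₁, Σ₂, CSP
finds spatial filters *w* extremizing the variance ratio
*w*ᵀΣ₁*w* / (*w*ᵀ(Σ₁+Σ₂)*w*) via the generalized eigendecomposition
Σ₁*v* = λ(Σ₁+Σ₂)*v*. With S = W M (W the L×N filter matrix, M an N×T
trial), the first J rows of W maximize class-1 variance and the last J rows
class-2 variance; the package uses L = 2J = 6 filters and log-normalized
variance features log(var_j / Σ_k var_k) fed to a linear SVM. Accuracy is
estimated by bootstrap resampling: 200 random 20/10 splits of a subject's 30
trials, or 70/30 splits of a pooled multi-subject trial set, refitting CSP
and the classifier on each repetition's training trials only.

The package provides:

- `mibci.simulate` — sessions with the protocol's structure (15+15 cues,
  10-s imagery + 5-s rest, distance levels 1–3), lateralized multiplicative
  ERD of configurable depth over C3/C4, 1/f spatially-mixed background,
  artifact bursts, and an 8-channel EMG surrogate; deterministic per seed.
- `mibci.preprocessing` — zero-phase band-pass, per-channel mean removal,
  Welch alpha/beta band power, artifact subspace reconstruction (ASR), and
  cue-locked epoching.
- `mibci.csp` — class covariances, CSP fitting, features, per-filter
  activity summaries.
- `mibci.protocols` — per-subject / pooled / per-level bootstraps,
  window-length and time-from-cue sweeps, with bit-reproducible seeding.
- `mibci.emg` — band-pass + rectification + mean absolute value (MAV).
- `mibci.stats` — Shapiro–Wilk-gated paired t / Wilcoxon comparison.
- `mibci.io` — 16-bit EDF and CSV writers/readers with JSON marker sidecars.
- a `mibci` command-line interface wrapping the stages
  (`simulate`, `preprocess`, `fit-csp`, `evaluate`, `sweep`, `emg-mav`,
  `compare`).

See `docs/methods.md` for the models, defaults, and numerical choices.

## Worked example

```python
import mibci

# a high-SNR subject: deep contralateral ERD, low background noise
cfg = mibci.SimConfig(erd_depth=0.8, noise_scale=2.0, artifact_rate=0.0, seed=7)
rec, truth = mibci.simulate_session(cfg)

clean = mibci.preprocess_pipeline(rec)          # band-pass + zero-mean
epochs = mibci.epoch(clean, 0.0, 10.0)          # 30 x 11 x 1250 cue windows

model = mibci.fit_csp_epochs(epochs, J=3)
print("kept eigenvalues:", model.eigenvalues[[0, 1, 2, -3, -2, -1]].round(3))
print("top pattern peaks at:",
      model.channel_labels[abs(model.patterns[:, 0]).argmax()])

res = mibci.bootstrap_subject(epochs, reps=200, seed=1)
print(f"accuracy: {res.mean:.1f} +/- {res.sd:.1f} %")
```

prints

```
kept eigenvalues: [0.798 0.519 0.514 0.492 0.489 0.206]
top pattern peaks at: C3
accuracy: 100.0 +/- 0.7 %
```

The extreme eigenvalues (0.798 / 0.206) are the variance ratios of the two
most discriminative filters; the top filter's spatial pattern peaks at C3,
an electrode over a simulated ERD source, and 200 bootstrap repetitions of
the 20/10 split classify this subject nearly perfectly. With `erd_depth=0`
the same call sits at chance (~50%), and at the default `erd_depth=0.5`,
`noise_scale=8` it lands in the 75–80% range typical of novice motor-imagery
users.

The same pipeline from the shell:

```sh
mibci simulate --out data/ --seed 7 --subjects 3
mibci preprocess --in data/sub-01.edf --out data/clean-01.edf
mibci evaluate --in data/clean-01.edf --mode subject --reps 200 --seed 1 --out results/sub01
mibci sweep --in data/clean-01.edf --axis window --reps 50 --seed 1 --out results/winsweep
```

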