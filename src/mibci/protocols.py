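"""Evaluation protocols: linear SVM, bootstrap resampling, parameter sweeps.

All protocols refit the full feature pipeline (class covariances -> CSP ->
SVM with inner cross-validated regularization) on each repetition's training
trials only, so no information leaks from the held-out trials.  Every
repetition's random split is derived from ``(base_seed, repetition_index)``,
making whole-protocol reruns bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import CLASSES, EpochSet, Recording, concatenate_epochs
from .csp import FeatureMatrix, apply_csp, fit_csp_epochs
from .preprocessing import epoch

C_GRID = np.logspace(-3, 2, 6)


@dataclass
class BootstrapResult:
    """Per-repetition test accuracies (%) with summary statistics."""

    accuracies: np.ndarray
    n_reps: int
    split: str
    seed: int
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if len(self.accuracies) != self.n_reps:
            raise ValueError("accuracy vector length must equal n_reps")
        if np.any((self.accuracies < 0) | (self.accuracies > 100)):
            raise ValueError("accuracies must lie in [0, 100]")
        self.mean = float(self.accuracies.mean())
        self.sd = float(self.accuracies.std(ddof=1)) if self.n_reps > 1 else 0.0

    def summary(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "n_reps": self.n_reps,
                "split": self.split, "seed": self.seed}


@dataclass
class SweepResult:
    """Accuracy as a function of window length or cue offset."""

    axis: np.ndarray  # strictly increasing axis values (seconds)
    axis_name: str  # "window_s" or "offset_s"
    per_subject: pd.DataFrame  # subjects x axis values, mean accuracy (%)
    mean: np.ndarray = field(init=False)
    sd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis values must be strictly increasing")
        vals = self.per_subject.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 100)):
            raise ValueError("accuracies must lie in [0, 100]")
        self.mean = vals.mean(axis=0)
        self.sd = vals.std(axis=0, ddof=1) if vals.shape[0] > 1 else np.zeros(len(self.axis))


def _select_C(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
              n_folds: int = 5) -> float:
    """Inner stratified cross-validation over a log-spaced C grid."""
    _, counts = np.unique(y, return_counts=True)
    k = int(min(n_folds, counts.min()))
    if k < 2:
        return 1.0
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    folds = list(skf.split(X, y))
    best_c, best_acc = C_GRID[0], -1.0
    for c in C_GRID:
        acc = 0.0
        for tr, va in folds:
            sc = StandardScaler().fit(X[tr])
            clf = SVC(kernel="linear", C=c)
            clf.fit(sc.transform(X[tr]), y[tr])
            acc += (clf.predict(sc.transform(X[va])) == y[va]).mean()
        acc /= len(folds)
        if acc > best_acc:  # ties keep the smaller (earlier) C
            best_acc, best_c = acc, c
    return float(best_c)


def train_eval(train: FeatureMatrix, test: FeatureMatrix,
               rng: np.random.Generator | None = None,
               optimize_c: bool = False) -> float:
    """Fit a linear-kernel SVM and return test accuracy in percent.

    Features are standardized with training-set statistics before the SVM.
    The default keeps the SVM at its default regularization (C=1): selecting
    C by inner CV on 20-trial training sets turns selection noise into a
    systematic below-chance test bias on null data (winner's curse), which a
    calibrated evaluation protocol cannot afford.  ``optimize_c=True``
    enables stratified 5-fold inner CV over a log-spaced grid instead.
    """
    if len(np.unique(train.y)) < 2:
        raise ValueError("training set must contain both classes")
    if train.X.shape[1] != test.X.shape[1]:
        raise ValueError("feature dimensions differ between train and test")
    if rng is None:
        rng = np.random.default_rng(0)
    c = _select_C(train.X, train.y, rng) if optimize_c else 1.0
    scaler = StandardScaler().fit(train.X)
    clf = SVC(kernel="linear", C=c)
    clf.fit(scaler.transform(train.X), train.y)
    pred = clf.predict(scaler.transform(test.X))
    return 100.0 * float((pred == test.y).mean())


def _stratified_split(y: np.ndarray, n_train: int, rng: np.random.Generator,
                      groups: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Random stratified split with n_train total training trials.

    Strata are the classes, crossed with ``groups`` (subject tags) when
    given: pooled multi-subject splits must balance each subject's classes
    across train and test, otherwise subject-specific spatial structure
    turns chance class imbalances into a systematic below-chance test bias.
    The training quota is spread proportionally over strata; remainders go
    to randomly chosen strata so the total is exact.
    """
    if groups is None:
        strata = np.asarray(y)
    else:
        strata = np.array([f"{g}|{c}" for g, c in zip(groups, y)])
    uniq = np.unique(strata)
    frac = n_train / len(strata)
    sizes = {s: int(np.floor(frac * np.sum(strata == s))) for s in uniq}
    short = n_train - sum(sizes.values())
    for s in rng.permutation(uniq)[:short]:
        sizes[s] += 1
    train_idx, test_idx = [], []
    for s in uniq:
        idx = np.flatnonzero(strata == s)
        perm = rng.permutation(idx)
        train_idx.append(perm[: sizes[s]])
        test_idx.append(perm[sizes[s]:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def _one_repetition(epochs: EpochSet, train_idx: np.ndarray, test_idx: np.ndarray,
                    J: int, rng: np.random.Generator, optimize_c: bool) -> float:
    train_set = epochs.select(train_idx)
    test_set = epochs.select(test_idx)
    model = fit_csp_epochs(train_set, J=J)
    return train_eval(apply_csp(model, train_set), apply_csp(model, test_set),
                      rng, optimize_c=optimize_c)


def bootstrap_subject(epochs: EpochSet, n_train: int = 20, n_test: int = 10,
                      reps: int = 200, seed: int = 0, J: int = 3,
                      optimize_c: bool = False) -> BootstrapResult:
    """Per-subject bootstrap: random stratified n_train/n_test splits, CSP+SVM
    refit per repetition, accuracy on the held-out trials."""
    if epochs.n_trials != n_train + n_test:
        raise ValueError(
            f"expected {n_train + n_test} trials, got {epochs.n_trials}"
        )
    y = epochs.y
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    accs = np.empty(reps)
    for r in range(reps):
        rng = np.random.default_rng([seed, r])
        tr, te = _stratified_split(y, n_train, rng)
        accs[r] = _one_repetition(epochs, tr, te, J, rng, optimize_c)
    return BootstrapResult(accuracies=accs, n_reps=reps,
                           split=f"{n_train}/{n_test} stratified", seed=seed)


def bootstrap_global(epochs: EpochSet, train_frac: float = 0.7, reps: int = 200,
                     seed: int = 0, J: int = 3,
                     optimize_c: bool = False) -> BootstrapResult:
    """Pooled bootstrap: train_frac/(1-train_frac) splits at the trial level,
    stratified by subject and class."""
    y = epochs.y
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    n_train = int(round(train_frac * epochs.n_trials))
    groups = epochs.labels["subject"].to_numpy()
    accs = np.empty(reps)
    for r in range(reps):
        rng = np.random.default_rng([seed, r])
        tr, te = _stratified_split(y, n_train, rng, groups=groups)
        accs[r] = _one_repetition(epochs, tr, te, J, rng, optimize_c)
    return BootstrapResult(accuracies=accs, n_reps=reps,
                           split=f"{train_frac:.0%}/{1 - train_frac:.0%} stratified",
                           seed=seed)


def subject_seed(base_seed: int, subject_index: int) -> int:
    """Stable per-subject seed derivation used by the sweeps (< 2**31)."""
    return int(np.random.SeedSequence([base_seed, subject_index])
               .generate_state(1)[0] % (2**31))


def window_sweep(recordings: list[Recording], lengths: list[float] | None = None,
                 offset: float = 0.0, reps: int = 200, seed: int = 0,
                 J: int = 3, cue_duration: float = 10.0) -> SweepResult:
    """Per-subject bootstrap accuracy as a function of epoch window length.

    For each length, epochs are re-cut from cue onset (+ ``offset``) and the
    per-subject bootstrap is re-run.  The per-subject seed does not depend on
    the axis value, so the full-length point reproduces
    ``bootstrap_subject`` at ``subject_seed(seed, i)`` exactly.
    """
    if lengths is None:
        lengths = [float(k) for k in range(1, 11)]
    for ln in lengths:
        if offset + ln > cue_duration:
            raise ValueError(
                f"window of {ln} s at offset {offset} s exceeds the "
                f"{cue_duration} s cue"
            )
    rows = {}
    for i, rec in enumerate(recordings):
        s = subject_seed(seed, i)
        rows[rec.subject] = [
            bootstrap_subject(epoch(rec, offset, ln), reps=reps, seed=s, J=J).mean
            for ln in lengths
        ]
    per_subject = pd.DataFrame.from_dict(rows, orient="index", columns=list(lengths))
    return SweepResult(axis=np.array(lengths), axis_name="window_s",
                       per_subject=per_subject)


def onset_sweep(recordings: list[Recording], window: float = 5.0,
                offsets: list[float] | None = None, reps: int = 200, seed: int = 0,
                J: int = 3, cue_duration: float = 10.0) -> SweepResult:
    """Per-subject bootstrap accuracy as a function of time from cue,
    at a fixed window length."""
    if offsets is None:
        offsets = [float(k) for k in range(0, 6)]
    for off in offsets:
        if off + window > cue_duration:
            raise ValueError(
                f"offset {off} s + window {window} s exceeds the "
                f"{cue_duration} s cue"
            )
    rows = {}
    for i, rec in enumerate(recordings):
        s = subject_seed(seed, i)
        rows[rec.subject] = [
            bootstrap_subject(epoch(rec, off, window), reps=reps, seed=s, J=J).mean
            for off in offsets
        ]
    per_subject = pd.DataFrame.from_dict(rows, orient="index", columns=list(offsets))
    return SweepResult(axis=np.array(offsets), axis_name="offset_s",
                       per_subject=per_subject)


def level_classification(epochs: EpochSet, level: int, train_frac: float = 0.7,
                         reps: int = 200, seed: int = 0, J: int = 3) -> BootstrapResult:
    """Left-vs-right classification restricted to one distance level,
    under the pooled (global) protocol."""
    sub = epochs.select_level(level)
    return bootstrap_global(sub, train_frac=train_frac, reps=reps, seed=seed, J=J)


def pool_subjects(epoch_sets: list[EpochSet]) -> EpochSet:
    """Pool per-subject epochs into one trial set for the global protocols."""
    return concatenate_epochs(epoch_sets)


def sweep_monotonicity(result: SweepResult) -> float:
    """Spearman rank correlation of the cross-subject mean curve with its axis."""
    rho, _ = sstats.spearmanr(result.axis, result.mean)
    return float(rho)
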