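"""Common spatial patterns for binary motor-imagery classification.

CSP finds spatial filters w that extremize the ratio of class-conditional
variances w' S_left w / (w' S_left w + w' S_right w).  With S = W M (W the
L x N filter matrix, M an N x T trial), the first J rows of W maximize the
variance of the first class and the last J rows that of the second class.
The problem is solved by the generalized symmetric eigendecomposition of
(S_left, S_left + S_right): eigenvalues lie in [0, 1] and equal each filter's
variance ratio, and under this whitening convention W (S_left + S_right) W'
is the identity.

Features are the canonical log-normalized variances of the L filtered
signals; the paired spatial patterns A (the mixing columns) describe each
filter's scalp topography.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .containers import CLASSES, EpochSet

RIDGE_EPS = 1e-6


@dataclass
class CSPModel:
    """Fitted spatial filters.

    W is L x N (one filter per row, L = 2J), ``eigenvalues`` the full
    descending spectrum in [0, 1] of which W keeps the top J and bottom J,
    and ``patterns`` the N x L mixing columns paired with the rows of W.
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    patterns: np.ndarray
    J: int
    channel_labels: list[str]
    kept_eigenvalues: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kept_eigenvalues is None:
            lam = self.eigenvalues
            self.kept_eigenvalues = np.concatenate([lam[: self.J], lam[-self.J:]])

    @property
    def n_filters(self) -> int:
        return self.W.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "W": self.W.tolist(),
                "eigenvalues": self.eigenvalues.tolist(),
                "patterns": self.patterns.tolist(),
                "J": self.J,
                "channel_labels": self.channel_labels,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CSPModel":
        d = json.loads(text)
        return cls(
            W=np.array(d["W"]),
            eigenvalues=np.array(d["eigenvalues"]),
            patterns=np.array(d["patterns"]),
            J=d["J"],
            channel_labels=list(d["channel_labels"]),
        )


def trial_covariance(trial: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Sample covariance of one channels x samples trial, trace-normalized."""
    x = trial - trial.mean(axis=1, keepdims=True)
    cov = (x @ x.T) / x.shape[1]
    if normalize:
        tr = np.trace(cov)
        if tr <= 0:
            raise ValueError("trial has zero variance; covariance undefined")
        cov = cov / tr
    return cov


def class_covariances(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-class average of trace-normalized per-trial covariances.

    Returns (S_left, S_right), each symmetric PSD with trace 1 (up to the
    ridge added for numerical conditioning).
    """
    if epochs.n_samples <= epochs.n_channels:
        raise ValueError("epoch length must exceed the channel count")
    y = epochs.y
    out = []
    for cls in CLASSES:
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(f"need at least 2 trials of class {cls!r}, got {len(idx)}")
        covs = [trial_covariance(epochs.data[i]) for i in idx]
        avg = np.mean(covs, axis=0)
        avg = 0.5 * (avg + avg.T)
        # ridge keeps short-window 11-channel estimates invertible
        avg = avg + RIDGE_EPS * (np.trace(avg) / avg.shape[0]) * np.eye(avg.shape[0])
        out.append(avg)
    return out[0], out[1]


def fit_csp(sigma_left: np.ndarray, sigma_right: np.ndarray, J: int = 3,
            channel_labels: list[str] | None = None) -> CSPModel:
    """Extract 2J spatial filters from a pair of class covariance matrices.

    Solves the generalized eigenproblem S_left v = lambda (S_left + S_right) v;
    keeps the J largest- and J smallest-eigenvalue filters.  Each retained
    filter's variance ratio w S_left w' / (w S_left w' + w S_right w') equals
    its eigenvalue. Filter signs are fixed so the largest-|coefficient| entry
    of each row of W is positive.
    """
    sigma_left = np.asarray(sigma_left, dtype=float)
    sigma_right = np.asarray(sigma_right, dtype=float)
    for name, s in (("left", sigma_left), ("right", sigma_right)):
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError(f"{name} covariance must be square")
        if not np.allclose(s, s.T, atol=1e-10 * max(1.0, np.abs(s).max())):
            raise ValueError(f"{name} covariance must be symmetric")
    if sigma_left.shape != sigma_right.shape:
        raise ValueError("covariance shapes differ")
    n = sigma_left.shape[0]
    if 2 * J > n:
        raise ValueError(f"2J = {2 * J} filters exceed {n} channels")

    composite = sigma_left + sigma_right
    evals, evecs = linalg.eigh(sigma_left, composite)
    order = np.argsort(evals)[::-1]  # stable: equal eigenvalues keep input order
    evals = np.clip(evals[order], 0.0, 1.0)
    w_full = evecs[:, order].T  # rows are filters; W composite W' = I by eigh

    keep = np.concatenate([np.arange(J), np.arange(n - J, n)])
    W = w_full[keep].copy()
    # sign convention: largest-magnitude coefficient positive
    for r in range(W.shape[0]):
        j = np.argmax(np.abs(W[r]))
        if W[r, j] < 0:
            W[r] = -W[r]
    patterns = composite @ W.T  # inverse-transpose of w_full restricted to kept rows
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(n)]
    return CSPModel(W=W, eigenvalues=evals, patterns=patterns, J=J,
                    channel_labels=list(channel_labels))


def fit_csp_epochs(epochs: EpochSet, J: int = 3) -> CSPModel:
    """Convenience: class covariances + fit, with the epoch channel labels."""
    sl, sr = class_covariances(epochs)
    return fit_csp(sl, sr, J=J, channel_labels=epochs.channel_labels)


@dataclass
class FeatureMatrix:
    """Trials x L log-variance CSP features with class labels."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("X must be trials x L with one label per trial")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite")


def apply_csp(model: CSPModel, epochs: EpochSet) -> FeatureMatrix:
    """Spatially filter each trial and take log-normalized variance features.

    Per trial M: S = W M; feature j = log( var(S_j) / sum_k var(S_k) ).
    Scale-invariant by construction.
    """
    if epochs.channel_labels != model.channel_labels:
        raise ValueError(
            f"epoch channels {epochs.channel_labels} do not match model "
            f"channels {model.channel_labels}"
        )
    feats = np.empty((epochs.n_trials, model.n_filters))
    for i in range(epochs.n_trials):
        s = model.W @ epochs.data[i]
        v = s.var(axis=1)
        feats[i] = np.log(v / v.sum())
    return FeatureMatrix(X=feats, y=epochs.y)


def filter_activity(model: CSPModel, epochs: EpochSet,
                    by: tuple[str, ...] = ("class", "session")) -> "np.ndarray | object":
    """Across-trial mean variance of each filtered signal, grouped.

    Returns a pandas DataFrame with one row per group and one ``filter_k``
    column per spatial filter — the per-filter "activity" summary used to
    compare sessions and classes.
    """
    import pandas as pd

    if epochs.channel_labels != model.channel_labels:
        raise ValueError("epoch channels do not match model channels")
    variances = np.stack([
        (model.W @ epochs.data[i]).var(axis=1) for i in range(epochs.n_trials)
    ])
    df = epochs.labels.copy()
    for k in range(model.n_filters):
        df[f"filter_{k + 1}"] = variances[:, k]
    cols = [f"filter_{k + 1}" for k in range(model.n_filters)]
    return df.groupby(list(by), sort=True)[cols].mean().reset_index()
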