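"""EEG conditioning chain: band-pass, zero-mean, band power, ASR, epoching.

The chain mirrors standard offline motor-imagery preprocessing: a zero-phase
band-pass per channel, per-channel mean removal, descriptive alpha/beta band
power, artifact subspace reconstruction (ASR) against a clean calibration
segment, and cue-locked epoch extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochSet, Recording

logger = logging.getLogger(__name__)

ALPHA_BAND = (7.0, 13.0)
BETA_BAND = (13.0, 30.0)


def bandpass_eeg(recording: Recording, lo: float = 4.0, hi: float = 70.0,
                 order: int = 4) -> Recording:
    """Zero-phase (forward-backward) Butterworth band-pass per channel.

    Raises if the upper edge reaches the Nyquist frequency; callers that want
    the clipping behaviour should use :func:`preprocess_pipeline`.
    """
    nyq = recording.fs / 2.0
    if not 0 < lo < hi:
        raise ValueError(f"band edges must satisfy 0 < lo < hi, got ({lo}, {hi})")
    if hi >= nyq:
        raise ValueError(
            f"upper band edge {hi} Hz reaches or exceeds the Nyquist frequency "
            f"{nyq} Hz at fs={recording.fs} Hz"
        )
    sos = signal.butter(order, [lo, hi], btype="band", fs=recording.fs, output="sos")
    out = recording.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=1)
    return out


def zero_mean(recording: Recording) -> Recording:
    """Remove the per-channel sample mean over the whole recording."""
    out = recording.copy()
    out.data = out.data - out.data.mean(axis=1, keepdims=True)
    return out


@dataclass
class BandPowerReport:
    """Per-trial, per-channel power (microvolt^2) integrated over named bands."""

    power: dict[str, np.ndarray]  # band name -> trials x channels
    bands: dict[str, tuple[float, float]]
    fs: float
    channel_labels: list[str]
    nperseg: int
    noverlap: int

    def mean_power(self, band: str) -> np.ndarray:
        """Across-trial mean power per channel for one band."""
        return self.power[band].mean(axis=0)


def band_power(epochs: EpochSet, bands: dict[str, tuple[float, float]] | None = None,
               segment_s: float = 1.0) -> BandPowerReport:
    """Welch band power per trial and channel.

    Modified periodograms on Hann segments of ``segment_s`` seconds with 50%
    overlap, averaged, then integrated over each requested band.
    """
    if bands is None:
        bands = {"alpha": ALPHA_BAND, "beta": BETA_BAND}
    nyq = epochs.fs / 2.0
    for name, (lo, hi) in bands.items():
        if not 0 < lo < hi < nyq:
            raise ValueError(f"band {name!r} = ({lo}, {hi}) Hz outside (0, {nyq}) Hz")
    nperseg = int(round(segment_s * epochs.fs))
    if epochs.n_samples < 2 * nperseg - nperseg // 2:
        raise ValueError("epochs shorter than two estimation segments")
    noverlap = nperseg // 2
    freqs, psd = signal.welch(
        epochs.data, fs=epochs.fs, window="hann", nperseg=nperseg,
        noverlap=noverlap, axis=2,
    )
    power = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        power[name] = np.trapezoid(psd[:, :, sel], freqs[sel], axis=2)
    return BandPowerReport(
        power=power, bands=dict(bands), fs=epochs.fs,
        channel_labels=list(epochs.channel_labels),
        nperseg=nperseg, noverlap=noverlap,
    )


@dataclass
class ASRState:
    """Calibration statistics for artifact subspace reconstruction.

    ``basis`` holds the principal axes (eigenvectors, columns) of the
    calibration covariance; ``thresholds`` the per-component RMS rejection
    threshold (calibration mean + k * SD of windowed component RMS).
    """

    basis: np.ndarray
    thresholds: np.ndarray
    cutoff_k: float
    window_s: float
    fs: float
    n_channels: int


def asr_calibrate(recording: Recording, window_s: float = 0.5,
                  cutoff_k: float = 20.0) -> ASRState:
    """Estimate the clean-data subspace statistics from a calibration recording.

    The calibration segment is assumed artifact-free (e.g. simulated rest).
    Requires at least one full window; in practice >= 30 s is recommended.
    """
    if cutoff_k <= 0:
        raise ValueError("cutoff_k must be positive")
    win = int(round(window_s * recording.fs))
    if recording.n_samples < win:
        raise ValueError(
            f"calibration of {recording.duration:.2f} s shorter than one "
            f"{window_s} s window"
        )
    x = recording.data - recording.data.mean(axis=1, keepdims=True)
    cov = (x @ x.T) / x.shape[1]
    evals, basis = np.linalg.eigh(cov)
    # windowed component RMS over 50%-overlapping calibration windows
    comp = basis.T @ x
    hop = max(win // 2, 1)
    starts = range(0, comp.shape[1] - win + 1, hop)
    rms = np.stack([
        np.sqrt(np.mean(comp[:, s:s + win] ** 2, axis=1)) for s in starts
    ])
    thresholds = rms.mean(axis=0) + cutoff_k * rms.std(axis=0)
    return ASRState(
        basis=basis, thresholds=thresholds, cutoff_k=cutoff_k,
        window_s=window_s, fs=recording.fs, n_channels=recording.n_channels,
    )


def asr_clean(recording: Recording, state: ASRState) -> Recording:
    """Reconstruct artifact components window by window.

    The signal is processed in consecutive windows; in each window the data
    is projected onto the calibration principal axes, components whose RMS
    exceeds their calibration threshold are removed, and the window is
    reconstructed from the retained subspace. Windows with no flagged
    component pass through unchanged, so cleaning is idempotent on clean data.
    """
    if recording.n_channels != state.n_channels:
        raise ValueError("channel count differs from calibration")
    if recording.fs != state.fs:
        raise ValueError("sampling rate differs from calibration")
    win = int(round(state.window_s * recording.fs))
    out = recording.copy()
    n = out.n_samples
    for start in range(0, n, win):
        seg = out.data[:, start:start + win]
        if seg.shape[1] < 2:
            continue
        comp = state.basis.T @ seg
        rms = np.sqrt(np.mean(comp**2, axis=1))
        flagged = rms > state.thresholds
        if flagged.any():
            comp[flagged] = 0.0
            out.data[:, start:start + win] = state.basis @ comp
    return out


def epoch(recording: Recording, offset_from_cue: float, length: float) -> EpochSet:
    """Cut cue-locked windows ``[cue + offset, cue + offset + length)``.

    Half-open sample windows on a 0-based grid; offsets and lengths are
    rounded to the nearest sample. Labels are carried from the markers.
    """
    if length <= 0:
        raise ValueError("epoch length must be positive")
    fs = recording.fs
    off = int(round(offset_from_cue * fs))
    n_samp = int(round(length * fs))
    starts = np.array([m.onset + off for m in recording.markers])
    stops = starts + n_samp
    bad = [i for i, (a, b) in enumerate(zip(starts, stops))
           if a < 0 or b > recording.n_samples]
    if bad:
        raise ValueError(
            f"epoch window [{offset_from_cue}, {offset_from_cue + length}) s "
            f"exceeds the recording for trials {bad}"
        )
    data = np.stack([recording.data[:, a:b] for a, b in zip(starts, stops)])
    labels = pd.DataFrame(
        {
            "class": [m.label for m in recording.markers],
            "level": [m.level for m in recording.markers],
            "subject": recording.subject,
            "session": [m.session for m in recording.markers],
        }
    )
    return EpochSet(data=data, fs=fs, channel_labels=list(recording.channel_labels),
                    labels=labels)


def preprocess_pipeline(recording: Recording, lo: float = 4.0, hi: float = 70.0,
                        asr: bool = False, asr_state: ASRState | None = None,
                        window_s: float = 0.5, cutoff_k: float = 20.0) -> Recording:
    """Full continuous-signal chain: band-pass -> zero-mean -> optional ASR.

    The upper band edge is clipped to 0.95 * Nyquist with a warning when the
    requested edge is unrealizable at the recording's sampling rate (e.g.
    70 Hz at fs=125 Hz).
    """
    nyq = recording.fs / 2.0
    hi_eff = hi
    if hi >= 0.95 * nyq:
        hi_eff = 0.95 * nyq
        logger.warning(
            "upper band edge %.1f Hz unrealizable at fs=%.1f Hz; clipped to %.1f Hz",
            hi, recording.fs, hi_eff,
        )
    rec = bandpass_eeg(recording, lo, hi_eff)
    rec = zero_mean(rec)
    if asr:
        if asr_state is None:
            asr_state = asr_calibrate(rec, window_s=window_s, cutoff_k=cutoff_k)
        rec = asr_clean(rec, asr_state)
    return rec
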