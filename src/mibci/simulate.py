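"""Synthetic sensorimotor-rhythm EEG and forearm-EMG generator.

Emulates the structure an offline motor-imagery analysis assumes: a session of
cued left/right-hand imagery trials (10 s cue + 5 s rest, 15 trials per hand),
with lateralized event-related desynchronization (ERD) of the mu (~10 Hz) and
beta (~20 Hz) rhythms over the contralateral motor cortex (C3/C4), spatially
correlated 1/f background noise, and optional high-amplitude artifact bursts.
Every output is deterministic given the configuration seed, and each session
comes with a ground-truth trial table.

The ERD model is multiplicative: a band-limited oscillator source located at
C3 (resp. C4) is scaled by ``1 - erd_depth`` during the cue window of trials
whose imagined hand is contralateral to it.  The source projects to
neighbouring channels with a fixed spatial falloff, so the amplitude reduction
appears, attenuated, on neighbours as well.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import Marker, Recording

DEFAULT_MONTAGE = [
    "Fp1", "Fpz", "Fp2", "F3", "F4", "Fz", "Fc1", "Fc2", "C3", "C4", "Cz",
]

# Scalp projection of the two sensorimotor sources: unit weight at the source
# electrode, fixed falloff to neighbours. No forward head model is attempted.
_SOURCE_TOPOGRAPHY = {
    "C3": {"C3": 1.0, "Cz": 0.35, "Fc1": 0.30, "F3": 0.20},
    "C4": {"C4": 1.0, "Cz": 0.35, "Fc2": 0.30, "F4": 0.20},
}


@dataclass(frozen=True)
class SimConfig:
    """Session-level simulation parameters (EEG in microvolts).

    ``erd_depth`` is the fractional mu/beta amplitude reduction contralateral
    to the imagined hand; ``erd_onset`` delays the start of the
    desynchronization relative to the cue (seconds).
    """

    n_channels: int = 11
    channel_labels: tuple[str, ...] = tuple(DEFAULT_MONTAGE)
    fs_eeg: float = 125.0
    fs_emg: float = 200.0
    n_trials_per_class: int = 15
    cue_duration: float = 10.0
    rest_duration: float = 5.0
    erd_depth: float = 0.5
    erd_onset: float = 0.0
    mu_freq: float = 10.0
    beta_freq: float = 20.0
    mu_amp: float = 1.5
    beta_amp: float = 0.8
    noise_scale: float = 8.0
    noise_exponent: float = 1.0
    artifact_rate: float = 0.5  # bursts per minute
    artifact_amp: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.cue_duration <= 0:
            raise ValueError("cue_duration must be positive")
        if self.n_trials_per_class < 1:
            raise ValueError("need at least one trial per class")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal n_channels")
        if len(set(self.channel_labels)) != self.n_channels:
            raise ValueError("channel_labels must be unique")
        if not 0 <= self.erd_onset < self.cue_duration:
            raise ValueError("erd_onset must lie within the cue window")
        for src in _SOURCE_TOPOGRAPHY:
            if src not in self.channel_labels:
                raise ValueError(
                    f"montage must include {src}: lateralized ERD is undefined without it"
                )


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-variance noise with power spectral density ~ 1/f**exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    # amplitude ~ f^(-exponent/2) gives PSD slope -exponent
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband(rng: np.random.Generator, n: int, fs: float, f0: float,
                half_width: float = 1.0) -> np.ndarray:
    """Unit-RMS band-limited oscillator: filtered Gaussian noise around f0."""
    lo = max(f0 - half_width, 0.1)
    hi = min(f0 + half_width, 0.49 * fs)
    sos = signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n + int(2 * fs)))[int(2 * fs):]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _mixing_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Near-orthonormal spatial mixing for the background noise sources."""
    q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    return q


def simulate_session(config: SimConfig, session: str = "MI1",
                     subject: str = "sub-01") -> tuple[Recording, pd.DataFrame]:
    """Generate one continuous motor-imagery session with ground truth.

    Returns the continuous :class:`Recording` (markers included) and a trial
    table with columns ``trial, onset_s, class, level, session, subject``.
    Left/right cues appear in randomized order, balanced per class, with the
    distance level cycling 1,2,3 within each class (5 trials per level per
    class at the default 15 trials per hand).
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs_eeg
    labels = list(config.channel_labels)
    n_ch = config.n_channels

    n_trials = 2 * config.n_trials_per_class
    trial_len = int(round((config.cue_duration + config.rest_duration) * fs))
    cue_len = int(round(config.cue_duration * fs))
    n_samples = n_trials * trial_len + int(round(config.rest_duration * fs))

    # Randomized class order, balanced; level cycles 1,2,3 within each class.
    classes = ["left"] * config.n_trials_per_class + ["right"] * config.n_trials_per_class
    order = rng.permutation(n_trials)
    classes = [classes[i] for i in order]
    level_counter = {"left": 0, "right": 0}
    levels = []
    for c in classes:
        levels.append(1 + level_counter[c] % 3)
        level_counter[c] += 1

    onsets = [t * trial_len for t in range(n_trials)]
    markers = [
        Marker(onset=o, label=c, level=lv, session=session)
        for o, c, lv in zip(onsets, classes, levels)
    ]

    # Background: independent 1/f sources through a fixed spatial mixing.
    mix = _mixing_matrix(rng, n_ch)
    sources = np.stack([
        _pink_noise(rng, n_samples, config.noise_exponent) for _ in range(n_ch)
    ])
    data = config.noise_scale * (mix @ sources)

    # Sensorimotor rhythms at C3/C4 with contralateral multiplicative ERD.
    erd_start = int(round(config.erd_onset * fs))
    envelopes = {"C3": np.ones(n_samples), "C4": np.ones(n_samples)}
    contralateral = {"left": "C4", "right": "C3"}
    for m in markers:
        src = contralateral[m.label]
        a = m.onset + erd_start
        b = m.onset + cue_len
        envelopes[src][a:b] = 1.0 - config.erd_depth
    for src, topo in _SOURCE_TOPOGRAPHY.items():
        rhythm = (config.mu_amp * _narrowband(rng, n_samples, fs, config.mu_freq)
                  + config.beta_amp * _narrowband(rng, n_samples, fs, config.beta_freq))
        rhythm = rhythm * envelopes[src]
        for ch, w in topo.items():
            data[labels.index(ch)] += w * rhythm

    # Occasional high-amplitude artifact bursts on random channel subsets.
    minutes = n_samples / fs / 60.0
    n_bursts = rng.poisson(config.artifact_rate * minutes)
    burst_len = int(round(0.5 * fs))
    for _ in range(n_bursts):
        start = int(rng.integers(0, n_samples - burst_len))
        chans = rng.choice(n_ch, size=int(rng.integers(1, 4)), replace=False)
        env = signal.windows.hann(burst_len)
        for ch in chans:
            data[ch, start:start + burst_len] += (
                config.artifact_amp * env * rng.standard_normal(burst_len)
            )

    rec = Recording(data=data, fs=fs, channel_labels=labels,
                    markers=markers, subject=subject)
    truth = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "onset_s": np.array(onsets) / fs,
            "class": classes,
            "level": levels,
            "session": session,
            "subject": subject,
        }
    )
    return rec, truth


def simulate_cohort(config: SimConfig, n_subjects: int = 10, seed: int = 0,
                    session: str = "MI1") -> list[Recording]:
    """Independent sessions for ``n_subjects`` subjects, seeds derived from ``seed``."""
    recs = []
    for i in range(n_subjects):
        sub_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        cfg = dataclasses.replace(config, seed=sub_seed)
        rec, _ = simulate_session(cfg, session=session, subject=f"sub-{i + 1:02d}")
        recs.append(rec)
    return recs


def simulate_emg(duration: float, burst_amplitude: float = 5.0, active: bool = False,
                 seed: int = 0, fs: float = 200.0, n_channels: int = 8,
                 noise_sigma: float = 1.0) -> Recording:
    """8-channel forearm-EMG surrogate at 200 Hz.

    Baseline is Gaussian sensor noise; ``active=True`` adds band-limited
    (20 Hz - 0.45*fs) contraction bursts of RMS ``burst_amplitude`` under a
    periodic on/off envelope, on top of the same baseline noise.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    data = noise_sigma * rng.standard_normal((n_channels, n))
    if active:
        t = np.arange(n) / fs
        # 1 s contraction / 1 s release cycle
        env = 0.5 * (1.0 - np.cos(2 * np.pi * 0.5 * t)) ** 2
        for ch in range(n_channels):
            burst = _narrowband(rng, n, fs, f0=0.25 * fs, half_width=0.2 * fs)
            data[ch] += burst_amplitude * env * burst
    labels = [f"EMG{i + 1}" for i in range(n_channels)]
    return Recording(data=data, fs=fs, channel_labels=labels)


def inject_artifact(recording: Recording, onset: float, duration: float,
                    amplitude: float, seed: int = 0) -> Recording:
    """Copy of ``recording`` with a high-amplitude burst on a random channel subset.

    ``onset``/``duration`` are seconds; the burst is Hann-windowed broadband
    noise of peak scale ``amplitude`` (microvolts). The input is not modified.
    """
    fs = recording.fs
    a = int(round(onset * fs))
    b = a + int(round(duration * fs))
    if onset < 0 or duration <= 0 or b > recording.n_samples:
        raise ValueError(
            f"artifact interval [{onset}, {onset + duration}) s outside recording "
            f"of {recording.duration:.2f} s"
        )
    rng = np.random.default_rng(seed)
    out = recording.copy()
    n_aff = int(rng.integers(1, min(3, recording.n_channels) + 1))
    chans = rng.choice(recording.n_channels, size=n_aff, replace=False)
    env = signal.windows.hann(b - a)
    for ch in chans:
        out.data[ch, a:b] += amplitude * env * rng.standard_normal(b - a)
    return out
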