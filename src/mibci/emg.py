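"""Forearm-EMG amplitude analysis: band-pass, rectification, mean absolute value.

MAV — the time-average of the full-wave-rectified signal — is the standard
surface-EMG amplitude feature; here it is computed per 8-channel armband and
averaged across arms to give one overall muscle-activity figure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import Recording

logger = logging.getLogger(__name__)


def emg_filter_rectify(recording: Recording, lo: float = 10.0, hi: float = 500.0,
                       order: int = 4) -> Recording:
    """Zero-phase band-pass then full-wave rectification.

    An upper edge at or beyond 0.95 * Nyquist (e.g. the conventional 500 Hz
    at a 200 Hz armband rate) is clipped to 0.95 * Nyquist with a warning.
    """
    nyq = recording.fs / 2.0
    hi_eff = hi
    if hi > 0.95 * nyq:
        hi_eff = 0.95 * nyq
        logger.warning(
            "EMG upper band edge %.0f Hz unrealizable at fs=%.0f Hz; "
            "clipped to %.1f Hz", hi, recording.fs, hi_eff,
        )
    if not 0 < lo < hi_eff:
        raise ValueError(
            f"invalid EMG band ({lo}, {hi_eff}) Hz after clipping at fs={recording.fs}"
        )
    sos = signal.butter(order, [lo, hi_eff], btype="band", fs=recording.fs,
                        output="sos")
    out = recording.copy()
    out.data = np.abs(signal.sosfiltfilt(sos, out.data, axis=1))
    return out


@dataclass
class MAVReport:
    """Per-arm mean absolute value (microvolts) and their cross-arm average."""

    mav_left: float
    mav_right: float
    band: tuple[float, float]
    condition: str = ""
    mav_average: float = field(init=False)

    def __post_init__(self) -> None:
        if self.mav_left < 0 or self.mav_right < 0:
            raise ValueError("MAV must be nonnegative")
        self.mav_average = 0.5 * (self.mav_left + self.mav_right)

    def to_dict(self) -> dict:
        return {
            "mav_left": self.mav_left,
            "mav_right": self.mav_right,
            "mav_average": self.mav_average,
            "band_hz": list(self.band),
            "condition": self.condition,
        }


def mav_value(recording: Recording) -> float:
    """Mean of the rectified samples across all channels and time."""
    return float(np.abs(recording.data).mean())


def mav(recording_left: Recording, recording_right: Recording,
        band: tuple[float, float] = (10.0, 500.0), condition: str = "") -> MAVReport:
    """MAV per arm (channels averaged within the armband) and across arms.

    Inputs are expected already filtered and rectified
    (:func:`emg_filter_rectify`); rectification is re-applied harmlessly by
    taking absolute values in the mean.
    """
    if recording_left.n_samples != recording_right.n_samples:
        raise ValueError(
            f"arm recordings differ in duration: {recording_left.n_samples} vs "
            f"{recording_right.n_samples} samples"
        )
    return MAVReport(
        mav_left=mav_value(recording_left),
        mav_right=mav_value(recording_right),
        band=band,
        condition=condition,
    )


def emg_chain(recording_left: Recording, recording_right: Recording,
              lo: float = 10.0, hi: float = 500.0, condition: str = "") -> MAVReport:
    """Full chain: band-pass + rectify each arm, then the MAV report."""
    fl = emg_filter_rectify(recording_left, lo, hi)
    fr = emg_filter_rectify(recording_right, lo, hi)
    return mav(fl, fr, band=(lo, hi), condition=condition)
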