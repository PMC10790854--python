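"""Core data containers: continuous recordings and cue-locked epoch sets.

A :class:`Recording` is a continuous multichannel signal in microvolts with a
sampling rate and a list of cue markers.  An :class:`EpochSet` is the
trials x channels x samples array cut from a recording, carrying per-trial
labels (imagined hand, plate-distance level, subject, session).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CLASSES = ("left", "right")
LEVELS = (1, 2, 3)


@dataclass(frozen=True)
class Marker:
    """A cue event: trial onset in samples, imagined hand, distance level."""

    onset: int
    label: str  # "left" or "right"
    level: int  # plate distance level, 1..3
    session: str = "S1"

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"marker label must be one of {CLASSES}, got {self.label!r}")
        if self.level not in LEVELS:
            raise ValueError(f"marker level must be one of {LEVELS}, got {self.level!r}")


@dataclass
class Recording:
    """Continuous multichannel signal (channels x samples, microvolts)."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    markers: list[Marker] = field(default_factory=list)
    subject: str = "sub-01"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording data must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = self.data.shape[1]
        onsets = [m.onset for m in self.markers]
        if any(o < 0 or o >= n for o in onsets):
            raise ValueError("marker onsets must lie within [0, n_samples)")
        if onsets != sorted(onsets):
            raise ValueError("markers must be sorted by onset")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(), markers=list(self.markers))

    def marker_table(self) -> pd.DataFrame:
        """Markers as a data frame (onset_s, class, level, session, subject)."""
        return pd.DataFrame(
            {
                "onset_s": [m.onset / self.fs for m in self.markers],
                "class": [m.label for m in self.markers],
                "level": [m.level for m in self.markers],
                "session": [m.session for m in self.markers],
                "subject": self.subject,
            }
        )


@dataclass
class EpochSet:
    """Cue-locked trials: data is trials x channels x samples.

    ``labels`` has one row per trial with columns
    ``class`` / ``level`` / ``subject`` / ``session``.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label row per trial required")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel label count must match data")
        required = {"class", "level", "subject", "session"}
        missing = required - set(self.labels.columns)
        if missing:
            raise ValueError(f"labels missing columns: {sorted(missing)}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def y(self) -> np.ndarray:
        """Class labels as a string array aligned with ``data``."""
        return self.labels["class"].to_numpy()

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset trials by boolean mask or integer index array."""
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            labels=self.labels.iloc[mask].reset_index(drop=True),
        )

    def select_level(self, level: int) -> "EpochSet":
        if level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        mask = (self.labels["level"] == level).to_numpy()
        if not mask.any():
            raise ValueError(f"no trials at level {level}")
        return self.select(mask)


def concatenate_epochs(epoch_sets: list[EpochSet]) -> EpochSet:
    """Pool trials across subjects/sessions (channel order must match)."""
    if not epoch_sets:
        raise ValueError("need at least one EpochSet")
    first = epoch_sets[0]
    for es in epoch_sets[1:]:
        if es.channel_labels != first.channel_labels:
            raise ValueError("channel labels differ across epoch sets")
        if es.fs != first.fs:
            raise ValueError("sampling rates differ across epoch sets")
        if es.n_samples != first.n_samples:
            raise ValueError("epoch lengths differ across epoch sets")
    return EpochSet(
        data=np.concatenate([es.data for es in epoch_sets], axis=0),
        fs=first.fs,
        channel_labels=list(first.channel_labels),
        labels=pd.concat([es.labels for es in epoch_sets], ignore_index=True),
    )
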