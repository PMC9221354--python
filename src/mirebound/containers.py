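"""Core in-memory containers shared across the pipeline.

The containers are deliberately thin: plain arrays plus the metadata needed to
interpret them (sampling rate, channel labels, epoch time axis, per-trial
labels).  Validation happens at construction so downstream stages can assume
consistent shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "EpochSet",
    "BandPowerTimeCourse",
    "ERDSTrace",
]


def _as_unique_labels(labels: Sequence[str]) -> list[str]:
    labels = [str(c) for c in labels]
    if len(set(labels)) != len(labels):
        raise ValueError("channel labels must be unique")
    return labels


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in volts (arbitrary units accepted).
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        10-20 system channel names, unique.
    events : list of (int, str)
        ``(sample_index, label)`` markers; indices must lie inside the data.
    bad_channels : list of str
        Channels excluded from the common average (caller-provided).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)
    bad_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        self.channel_labels = _as_unique_labels(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.data.shape[1]
        self.events = [(int(s), str(lbl)) for s, lbl in self.events]
        for s, _ in self.events:
            if not (0 <= s < n):
                raise ValueError(f"event sample index {s} outside recording")
        unknown = set(self.bad_channels) - set(self.channel_labels)
        if unknown:
            raise ValueError(f"bad_channels not in montage: {sorted(unknown)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)


@dataclass
class EpochSet:
    """Stimulus-locked trials.

    ``data`` is trials x channels x samples; ``time_axis`` is in seconds with
    the stimulus at 0; ``labels`` is a DataFrame with one row per trial and
    (at least) columns ``condition`` (ME/MI), ``motion``, ``hand``
    (left/right/none) and ``subject``.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    time_axis: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be 3-D (trials x channels x samples)")
        self.channel_labels = _as_unique_labels(self.channel_labels)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        n_trials, n_ch, n_samp = self.data.shape
        if n_ch != len(self.channel_labels):
            raise ValueError("channel_labels length must match data channels")
        if len(self.time_axis) != n_samp:
            raise ValueError("time_axis length must match data samples")
        if len(self.labels) != n_trials:
            raise ValueError("labels must have one row per trial")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None

    def pick_channels(self, labels: Sequence[str]) -> "EpochSet":
        idx = [self.channel_index(c) for c in labels]
        return EpochSet(
            data=self.data[:, idx, :],
            fs=self.fs,
            channel_labels=[self.channel_labels[i] for i in idx],
            time_axis=self.time_axis.copy(),
            labels=self.labels.reset_index(drop=True),
        )

    def crop(self, t0: float, t1: float) -> "EpochSet":
        """Restrict the epoch window to ``[t0, t1]`` (inclusive)."""
        if t0 < self.time_axis[0] - 1e-9 or t1 > self.time_axis[-1] + 1e-9:
            raise ValueError("crop interval outside epoch time axis")
        mask = (self.time_axis >= t0 - 1e-9) & (self.time_axis <= t1 + 1e-9)
        return EpochSet(
            data=self.data[:, :, mask],
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            time_axis=self.time_axis[mask],
            labels=self.labels.reset_index(drop=True),
        )

    def time_index(self, t: float) -> int:
        return int(np.argmin(np.abs(self.time_axis - t)))


@dataclass
class BandPowerTimeCourse:
    """Trial-averaged band power per channel over the epoch time axis."""

    power: np.ndarray  # channels x samples, uV^2
    band: tuple[float, float]
    n_trials: int
    fs: float
    time_axis: np.ndarray
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.power.ndim != 2:
            raise ValueError("power must be 2-D (channels x samples)")
        if self.power.shape[1] != len(self.time_axis):
            raise ValueError("power and time_axis lengths differ")
        if np.any(self.power < -1e-12):
            raise ValueError("band power must be non-negative")
        self.channel_labels = _as_unique_labels(self.channel_labels)

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None


@dataclass
class ERDSTrace:
    """ERD/ERS percentage time course per channel.

    ``values`` are in percent: negative = desynchronization (ERD), positive =
    synchronization (ERS).  ``significance`` is an optional boolean mask of the
    same shape marking samples whose bootstrap interval excludes zero.
    """

    values: np.ndarray  # channels x samples, percent
    reference_power: np.ndarray  # per channel, uV^2
    reference_interval: tuple[float, float]
    band: tuple[float, float]
    time_axis: np.ndarray
    channel_labels: list[str]
    significance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.reference_power = np.asarray(self.reference_power, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.time_axis):
            raise ValueError("values must be channels x samples matching time_axis")
        self.channel_labels = _as_unique_labels(self.channel_labels)
        if len(self.channel_labels) != self.values.shape[0]:
            raise ValueError("channel_labels length must match values rows")
        if self.significance is not None:
            self.significance = np.asarray(self.significance, dtype=bool)
            if self.significance.shape != self.values.shape:
                raise ValueError("significance mask shape mismatch")

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    def channel(self, label: str) -> np.ndarray:
        return self.values[self.channel_index(label)]
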