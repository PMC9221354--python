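"""Continuous-recording preprocessing: re-referencing, filtering, epoching.

The chain mirrors standard motor-imagery practice: common average reference,
zero-phase 1-60 Hz band-pass plus 50 Hz notch, stimulus-locked epoch
extraction and pre-stimulus baseline correction.  All filters are zero-phase
(forward-backward), so no stage introduces a latency bias into the rebound
timing statistics downstream.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochSet, Recording

__all__ = [
    "common_average_reference",
    "filter_signal",
    "extract_epochs",
    "baseline_correct",
]

logger = logging.getLogger(__name__)


def common_average_reference(rec: Recording) -> Recording:
    """Re-reference every channel against the mean of the non-bad channels.

    Bad channels are excluded from the average but re-expressed against it.
    Applying the operation twice equals applying it once.
    """
    good = [i for i, c in enumerate(rec.channel_labels) if c not in rec.bad_channels]
    if len(good) < 2:
        raise ValueError("common average reference needs >= 2 non-bad channels")
    avg = rec.data[good].mean(axis=0, keepdims=True)
    return rec.copy_with(data=rec.data - avg)


def _design_bandpass(band: tuple[float, float], fs: float, order: int = 4):
    return signal.butter(order, band, btype="bandpass", fs=fs, output="sos")


def filter_signal(
    rec: Recording,
    band: tuple[float, float] = (1.0, 60.0),
    notch: float | None = 50.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase band-pass (Butterworth, forward-backward) plus mains notch."""
    lo, hi = band
    if rec.fs <= 2.0 * hi:
        raise ValueError("sampling rate too low for the requested band")
    sos = _design_bandpass((lo, hi), rec.fs, order)
    out = signal.sosfiltfilt(sos, rec.data, axis=-1)
    if notch is not None:
        b, a = signal.iirnotch(notch, notch_q, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=-1)
    return rec.copy_with(data=out)


def extract_epochs(
    rec: Recording,
    window: tuple[float, float] = (-1.0, 4.0),
    event_filter: Callable[[str], bool] | Iterable[str] | None = None,
    label_columns: dict[str, str] | None = None,
) -> EpochSet:
    """Cut stimulus-locked epochs around the selected events.

    The window is a closed interval: ``samples = round((t1 - t0) * fs) + 1``
    with the stimulus at time 0.  Events whose window would cross a recording
    edge are dropped with a logged warning.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window end must exceed window start")
    if callable(event_filter):
        selected = [(s, lbl) for s, lbl in rec.events if event_filter(lbl)]
    elif event_filter is None:
        selected = list(rec.events)
    else:
        allowed = set(event_filter)
        selected = [(s, lbl) for s, lbl in rec.events if lbl in allowed]
    if not selected:
        raise ValueError("no events match the event filter")

    n_samples = int(round((t1 - t0) * rec.fs)) + 1
    offset = int(round(t0 * rec.fs))
    trials, kept = [], []
    for s, lbl in sorted(selected):
        start = s + offset
        stop = start + n_samples
        if start < 0 or stop > rec.n_samples:
            logger.warning("dropping epoch at sample %d: window crosses edge", s)
            continue
        trials.append(rec.data[:, start:stop])
        kept.append(lbl)
    if not trials:
        raise ValueError("all matching epochs cross the recording edges")

    extra = label_columns or {}
    labels = pd.DataFrame(
        {
            "condition": kept,
            "motion": [extra.get("motion", "M1")] * len(kept),
            "hand": [extra.get("hand", "none")] * len(kept),
            "subject": [extra.get("subject", "S01")] * len(kept),
        }
    )
    time_axis = t0 + np.arange(n_samples) / rec.fs
    return EpochSet(
        data=np.stack(trials),
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        time_axis=time_axis,
        labels=labels,
    )


def baseline_correct(epochs: EpochSet, interval: tuple[float, float] = (-1.0, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``interval``."""
    a, b = interval
    if a < epochs.time_axis[0] - 1e-9 or b > epochs.time_axis[-1] + 1e-9:
        raise ValueError("baseline interval outside the epoch time axis")
    mask = (epochs.time_axis >= a - 1e-9) & (epochs.time_axis <= b + 1e-9)
    if not mask.any():
        raise ValueError("baseline interval contains no samples")
    base = epochs.data[:, :, mask].mean(axis=-1, keepdims=True)
    return EpochSet(
        data=epochs.data - base,
        fs=epochs.fs,
        channel_labels=list(epochs.channel_labels),
        time_axis=epochs.time_axis.copy(),
        labels=epochs.labels.reset_index(drop=True),
    )
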