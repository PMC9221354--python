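"""Event-related desynchronization/synchronization (ERD/ERS) analysis.

The quantity is the classic percentage change of trial-averaged band power
relative to a task-free reference interval:

    ERD/ERS_i = (A_i - R) / R * 100

where ``A_i`` is the average power of the i-th sample over all trials and
``R`` the average power over the reference interval.  Negative values are ERD,
positive values ERS.  Significance is assessed with a percentile bootstrap
over trials.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .containers import BandPowerTimeCourse, EpochSet, ERDSTrace

__all__ = [
    "single_trial_band_power",
    "band_power_timecourse",
    "erders_timecourse",
    "bootstrap_significance",
    "condition_difference",
    "single_trial_erders",
]

#: default beta analysis band, Hz
BETA_BAND = (13.0, 40.0)
#: default pre-stimulus reference interval, s
REFERENCE_INTERVAL = (-1.0, -0.1)
#: default moving-average smoothing of the power time course, s
SMOOTH_WINDOW = 0.25


def single_trial_band_power(
    epochs: EpochSet,
    band: tuple[float, float] = BETA_BAND,
    smooth_window: float = SMOOTH_WINDOW,
) -> np.ndarray:
    """Smoothed instantaneous band power per trial (trials x channels x samples).

    Each trial is zero-phase band-pass filtered, squared, then smoothed with a
    moving average of ``smooth_window`` seconds.
    """
    lo, hi = band
    if hi >= epochs.fs / 2.0:
        raise ValueError("band upper edge must lie below Nyquist")
    if lo < 0.5:
        raise ValueError("band lower edge too low")
    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=epochs.fs, output="sos")
    # even (symmetric) padding: odd reflection flips the oscillation phase at
    # the boundary and cancels band power over the edge transient
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1, padtype="even")
    power = filtered**2
    width = max(1, int(round(smooth_window * epochs.fs)))
    if width > 1:
        power = uniform_filter1d(power, size=width, axis=-1, mode="nearest")
    return power


def band_power_timecourse(
    epochs: EpochSet,
    band: tuple[float, float] = BETA_BAND,
    smooth_window: float = SMOOTH_WINDOW,
) -> BandPowerTimeCourse:
    """Trial-averaged smoothed band power per channel."""
    if epochs.n_trials < 2:
        raise ValueError("band_power_timecourse needs >= 2 trials")
    power = single_trial_band_power(epochs, band, smooth_window).mean(axis=0)
    return BandPowerTimeCourse(
        power=power,
        band=tuple(band),
        n_trials=epochs.n_trials,
        fs=epochs.fs,
        time_axis=epochs.time_axis.copy(),
        channel_labels=list(epochs.channel_labels),
    )


def _reference_mask(time_axis: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    a, b = interval
    if a < time_axis[0] - 1e-9 or b > time_axis[-1] + 1e-9:
        raise ValueError("reference interval outside the time axis")
    mask = (time_axis >= a - 1e-9) & (time_axis <= b + 1e-9)
    if not mask.any():
        raise ValueError("reference interval contains no samples")
    return mask


def erders_timecourse(
    bp: BandPowerTimeCourse,
    reference_interval: tuple[float, float] = REFERENCE_INTERVAL,
) -> ERDSTrace:
    """Percentage band-power change relative to the reference interval."""
    mask = _reference_mask(bp.time_axis, reference_interval)
    ref = bp.power[:, mask].mean(axis=1)
    if np.any(ref <= 0):
        raise ValueError("degenerate reference: zero power in reference interval")
    values = (bp.power - ref[:, None]) / ref[:, None] * 100.0
    return ERDSTrace(
        values=values,
        reference_power=ref,
        reference_interval=tuple(reference_interval),
        band=bp.band,
        time_axis=bp.time_axis.copy(),
        channel_labels=list(bp.channel_labels),
    )


def bootstrap_significance(
    epochs: EpochSet,
    band: tuple[float, float] = BETA_BAND,
    reference_interval: tuple[float, float] = REFERENCE_INTERVAL,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    smooth_window: float = SMOOTH_WINDOW,
) -> np.ndarray:
    """Boolean mask of samples whose bootstrap ERD/ERS interval excludes 0.

    Trials are resampled with replacement ``n_boot`` times; the full ERD/ERS
    statistic (trial-averaged power, reference, percentage change) is
    recomputed on each resample and a percentile interval at ``level``
    confidence is formed per channel and sample.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if epochs.n_trials < 5:
        raise ValueError("bootstrap needs >= 5 trials")
    power = single_trial_band_power(epochs, band, smooth_window)
    mask = _reference_mask(epochs.time_axis, reference_interval)
    rng = np.random.default_rng(seed)
    n = epochs.n_trials
    alpha = (1.0 - level) / 2.0
    boots = np.empty((n_boot, epochs.n_channels, epochs.n_samples))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        a = power[idx].mean(axis=0)
        ref = a[:, mask].mean(axis=1)
        boots[b] = (a - ref[:, None]) / ref[:, None] * 100.0
    lo = np.quantile(boots, alpha, axis=0)
    hi = np.quantile(boots, 1.0 - alpha, axis=0)
    return (lo > 0.0) | (hi < 0.0)


def condition_difference(erds_me: ERDSTrace, erds_mi: ERDSTrace) -> ERDSTrace:
    """Elementwise ME - MI difference of two aligned ERD/ERS traces."""
    if erds_me.channel_labels != erds_mi.channel_labels:
        raise ValueError("channel sets differ")
    if erds_me.band != erds_mi.band:
        raise ValueError("bands differ")
    if erds_me.values.shape != erds_mi.values.shape or not np.allclose(
        erds_me.time_axis, erds_mi.time_axis
    ):
        raise ValueError("time axes differ")
    return ERDSTrace(
        values=erds_me.values - erds_mi.values,
        reference_power=np.full_like(erds_me.reference_power, np.nan),
        reference_interval=erds_me.reference_interval,
        band=erds_me.band,
        time_axis=erds_me.time_axis.copy(),
        channel_labels=list(erds_me.channel_labels),
    )


def single_trial_erders(
    epochs: EpochSet,
    band: tuple[float, float] = BETA_BAND,
    reference_interval: tuple[float, float] = REFERENCE_INTERVAL,
    smooth_window: float = SMOOTH_WINDOW,
) -> np.ndarray:
    """Per-trial normalized band-power series (trials x channels x samples, %).

    Single-trial analogue of the trial-averaged ERD/ERS statistic, used as the
    "ERD/ERS data" input of per-trial features (e.g. sample entropy).  Each
    trial's smoothed band power is normalized by that trial's own reference
    power.
    """
    power = single_trial_band_power(epochs, band, smooth_window)
    mask = _reference_mask(epochs.time_axis, reference_interval)
    ref = power[:, :, mask].mean(axis=-1)
    if np.any(ref <= 0):
        raise ValueError("degenerate reference: zero power in reference interval")
    return (power - ref[:, :, None]) / ref[:, :, None] * 100.0
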