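"""Synthetic EEG with known ERD/ERS structure.

The generator produces stimulus-locked epochs that carry the signatures the
downstream analysis looks for, with every parameter recorded as ground truth:

* a 1/f (spectrally shaped Gaussian) background on every channel;
* a band-limited sensorimotor oscillation on every channel whose amplitude
  envelope encodes (a) a pre-rebound event-related desynchronization (ERD)
  plateau on the configured ERD channels and (b) a Gaussian post-stimulus
  rebound bump (ERS) on the configured rebound channels;
* per-trial jitter of the rebound peak time.

The envelope is calibrated so that the *observable* trial-averaged ERD/ERS
percentage (band power relative to the pre-stimulus reference, Eq.-style
``(A - R)/R * 100``) matches the configured ``erd_depth`` and
``rebound_amplitude``: the broadband background leaks power into the analysis
band, so the oscillation modulation is scaled up by ``1 + band_fraction/snr^2``
to compensate for that dilution.  This makes the profile parameters directly
comparable to what the ERD/ERS stage measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet, Recording

__all__ = [
    "MONTAGE_1020",
    "ConditionProfile",
    "GroundTruth",
    "default_profiles",
    "generate_epochs",
    "generate_cohort",
    "epochs_to_recording",
]

#: 10-20 names accepted by the generator (32-channel actiCAP-style montage).
MONTAGE_1020 = (
    "Fp1 Fp2 F7 F3 Fz F4 F8 FC5 FC1 FC2 FC6 T7 C3 Cz C4 T8 "
    "CP5 CP1 CP2 CP6 P7 P3 Pz P4 P8 PO9 O1 Oz O2 PO10 TP9 TP10"
).split()

DEFAULT_CHANNELS = ["C3", "Cz", "C4", "FC1", "FC2", "CP1", "CP2"]


@dataclass
class ConditionProfile:
    """Ground-truth modulation parameters for one experimental condition.

    ``rebound_amplitude`` and ``erd_depth`` are in percent of reference band
    power (ERS positive, ERD non-positive); latency/duration in seconds
    (duration = full width at half amplitude of the rebound envelope).
    ``snr`` is the ratio of the baseline oscillation RMS to the broadband
    background RMS.
    """

    rebound_amplitude: float = 100.0
    rebound_latency: float = 1.6
    rebound_duration: float = 0.3
    erd_depth: float = -25.0
    erd_channels: list[str] = field(default_factory=lambda: ["C3", "C4"])
    rebound_channels: list[str] = field(default_factory=lambda: ["Cz"])
    band: tuple[float, float] = (13.0, 40.0)
    noise_1f_exponent: float = 1.0
    snr: float = 1.0
    latency_jitter_sd: float = 0.1
    erd_onset: float = 0.25

    def __post_init__(self) -> None:
        if self.rebound_amplitude < 0:
            raise ValueError("rebound_amplitude must be >= 0")
        if self.rebound_latency <= 0:
            raise ValueError("rebound_latency must be > 0")
        if self.rebound_duration <= 0:
            raise ValueError("rebound_duration must be > 0")
        if not (-100.0 <= self.erd_depth <= 0.0):
            raise ValueError("erd_depth must lie in [-100, 0]")
        lo, hi = self.band
        if not (1.0 <= lo < hi <= 60.0):
            raise ValueError("band must lie within [1, 60] Hz")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        for ch in list(self.erd_channels) + list(self.rebound_channels):
            if ch not in MONTAGE_1020:
                raise ValueError(f"unknown channel label {ch!r}")


@dataclass
class GroundTruth:
    """What was actually injected into a generated EpochSet."""

    profile: ConditionProfile
    seed: int
    peak_jitter: np.ndarray  # per-trial latency jitter, s


def default_profiles() -> dict[str, ConditionProfile]:
    """Default condition profiles for ME, MI and left/right-hand MI.

    The contrast encodes the qualitative ME/MI difference: the MI rebound has
    roughly a quarter of the ME amplitude, peaks later (1.8 s vs 1.6 s,
    matching the reported example peak times of 1.624 s and 1.818 s) and lasts
    longer.  The ME rebound spans Cz and its fronto/centro-parietal
    neighbours; the MI rebound is confined to Cz.  Left/right-hand MI profiles
    place the ERD on the contralateral central channel.
    """
    me = ConditionProfile(
        rebound_amplitude=100.0,
        rebound_latency=1.6,
        rebound_duration=0.3,
        erd_depth=-25.0,
        erd_channels=["C3", "C4"],
        rebound_channels=["Cz", "FC1", "FC2", "CP1", "CP2"],
    )
    mi = ConditionProfile(
        rebound_amplitude=25.0,  # ~25% of ME
        rebound_latency=1.8,
        rebound_duration=1.0,
        erd_depth=-25.0,
        erd_channels=["C3", "C4"],
        rebound_channels=["Cz"],
    )
    left = ConditionProfile(
        rebound_amplitude=25.0,
        rebound_latency=1.8,
        rebound_duration=1.0,
        erd_depth=-50.0,
        erd_channels=["C4"],
        rebound_channels=["Cz"],
    )
    right = ConditionProfile(
        rebound_amplitude=25.0,
        rebound_latency=1.8,
        rebound_duration=1.0,
        erd_depth=-50.0,
        erd_channels=["C3"],
        rebound_channels=["Cz"],
    )
    return {"ME": me, "MI": mi, "left": left, "right": right}


def _shaped_noise_weights(n_samples: int, fs: float, exponent: float) -> np.ndarray:
    """rFFT amplitude weights for 1/f^exponent noise, unit-variance normalized."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    w = np.zeros_like(freqs)
    f_floor = 1.0  # flatten the spectrum below 1 Hz to keep variance finite
    nz = freqs > 0
    w[nz] = np.maximum(freqs[nz], f_floor) ** (-exponent / 2.0)
    # expected time-domain variance of irfft(Z * w) with Z standard complex
    # normal (unit-variance real and imaginary parts)
    c = np.full_like(freqs, 2.0)
    c[0] = 1.0
    if n_samples % 2 == 0:
        c[-1] = 1.0
    var = 2.0 * np.sum(c * w**2) / n_samples**2
    return w / np.sqrt(var)


def _band_fraction(w: np.ndarray, n_samples: int, fs: float, band: tuple[float, float]) -> float:
    """Fraction of the shaped-noise power that falls inside ``band``."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    c = np.full_like(freqs, 2.0)
    c[0] = 1.0
    if n_samples % 2 == 0:
        c[-1] = 1.0
    total = np.sum(c * w**2)
    in_band = (freqs >= band[0]) & (freqs < band[1])
    return float(np.sum(c[in_band] * w[in_band] ** 2) / total)


def _smooth_box(t: np.ndarray, a: float, b: float, edge: float = 0.08) -> np.ndarray:
    """Smooth indicator of [a, b] with sigmoid edges of scale ``edge`` s."""
    if b <= a:
        return np.zeros_like(t)
    rise = 1.0 / (1.0 + np.exp(-(t - a) / edge))
    fall = 1.0 / (1.0 + np.exp(-(b - t) / edge))
    return rise * fall


def _target_modulation(
    profile: ConditionProfile,
    t: np.ndarray,
    channels: list[str],
    peak_times: np.ndarray,
) -> np.ndarray:
    """Per-trial, per-channel target ERD/ERS percentage g(t)."""
    n_trials = len(peak_times)
    g = np.zeros((n_trials, len(channels), len(t)))
    erd_end = profile.rebound_latency - profile.rebound_duration / 2.0
    erd = profile.erd_depth * _smooth_box(t, profile.erd_onset, erd_end)
    four_ln2 = 4.0 * np.log(2.0)
    # latency jitter broadens the ensemble-average bump (convolution of the
    # Gaussian envelope with the jitter distribution); scale the per-trial
    # amplitude so the *ensemble* ERS peak matches the configured amplitude
    sigma0 = profile.rebound_duration / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_j = np.hypot(sigma0, profile.latency_jitter_sd)
    amp = profile.rebound_amplitude * sigma_j / sigma0
    for j, pk in enumerate(peak_times):
        bump = amp * np.exp(
            -four_ln2 * (t - pk) ** 2 / profile.rebound_duration**2
        )
        for i, ch in enumerate(channels):
            if ch in profile.erd_channels:
                g[j, i] += erd
            if ch in profile.rebound_channels:
                g[j, i] += bump
    return g


def generate_epochs(
    profile: ConditionProfile,
    n_trials: int,
    channels: list[str] | None = None,
    fs: float = 250.0,
    window: tuple[float, float] = (-1.0, 4.0),
    seed: int = 0,
    *,
    condition: str = "ME",
    motion: str = "M1",
    hand: str = "none",
    subject: str = "S01",
    amplitude_scale: float = 10.0,
) -> tuple[EpochSet, GroundTruth]:
    """Generate stimulus-locked synthetic epochs for one condition.

    Identical ``seed`` gives bit-identical output.  The epoch window must
    include a pre-stimulus interval and cover the configured rebound latency.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    channels = list(DEFAULT_CHANNELS if channels is None else channels)
    for ch in channels:
        if ch not in MONTAGE_1020:
            raise ValueError(f"unknown channel label {ch!r}")
    t0, t1 = window
    if t0 >= 0:
        raise ValueError("window must start before the stimulus (t0 < 0)")
    if t1 < profile.rebound_latency:
        raise ValueError("rebound outside epoch")
    if fs <= 2.0 * profile.band[1]:
        raise ValueError("fs must exceed twice the upper band edge")

    n_samples = int(round((t1 - t0) * fs)) + 1
    t = t0 + np.arange(n_samples) / fs
    rng = np.random.default_rng(seed)

    # background: independent unit-variance 1/f noise per trial and channel
    w = _shaped_noise_weights(n_samples, fs, profile.noise_1f_exponent)
    nf = len(w)
    z = rng.standard_normal((n_trials, len(channels), nf)) + 1j * rng.standard_normal(
        (n_trials, len(channels), nf)
    )
    noise = np.fft.irfft(z * w, n=n_samples, axis=-1)

    # oscillation: sinusoidal carrier with per-trial frequency/phase and an
    # amplitude envelope calibrated against band leakage of the background
    band_frac = _band_fraction(w, n_samples, fs, profile.band)
    kappa = 1.0 + band_frac / profile.snr**2  # dilution compensation
    a0 = np.sqrt(2.0) * profile.snr  # baseline amplitude for unit noise RMS

    jitter = rng.normal(0.0, profile.latency_jitter_sd, size=n_trials)
    peak_times = profile.rebound_latency + jitter
    g = _target_modulation(profile, t, channels, peak_times)
    envelope = a0 * np.sqrt(np.clip(1.0 + kappa * g / 100.0, 0.0, None))

    f_center = 0.5 * (profile.band[0] + profile.band[1])
    f_trial = f_center + rng.uniform(-2.0, 2.0, size=n_trials)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=(n_trials, len(channels)))
    carrier = np.cos(
        2.0 * np.pi * f_trial[:, None, None] * t[None, None, :] + phase[:, :, None]
    )

    data = amplitude_scale * (noise + envelope * carrier)
    labels = pd.DataFrame(
        {
            "condition": [condition] * n_trials,
            "motion": [motion] * n_trials,
            "hand": [hand] * n_trials,
            "subject": [subject] * n_trials,
        }
    )
    epochs = EpochSet(
        data=data, fs=fs, channel_labels=channels, time_axis=t, labels=labels
    )
    truth = GroundTruth(profile=profile, seed=int(seed), peak_jitter=jitter)
    return epochs, truth


def generate_cohort(
    profiles: dict[str, ConditionProfile],
    n_trials: int = 40,
    channels: list[str] | None = None,
    fs: float = 250.0,
    window: tuple[float, float] = (-1.0, 4.0),
    seed: int = 0,
    *,
    subject: str = "S01",
    motion: str = "M1",
) -> dict[str, tuple[EpochSet, GroundTruth]]:
    """Generate one EpochSet per named condition with independent sub-seeds."""
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[EpochSet, GroundTruth]] = {}
    hands = {"left": "left", "right": "right"}
    for name, profile in profiles.items():
        sub_seed = int(rng.integers(0, 2**31))
        out[name] = generate_epochs(
            profile,
            n_trials,
            channels,
            fs,
            window,
            sub_seed,
            condition="MI" if name in ("MI", "left", "right") else "ME",
            motion=motion,
            hand=hands.get(name, "none"),
            subject=subject,
        )
    return out


def epochs_to_recording(
    epochs: EpochSet, gap: float = 0.5, seed: int = 0
) -> Recording:
    """Concatenate epochs into a continuous pseudo-recording with markers.

    Trials are separated by ``gap`` seconds of low-amplitude noise; one event
    per trial is placed at the stimulus sample (time 0 of the epoch axis).
    Useful for exercising the preprocessing path end to end.
    """
    rng = np.random.default_rng(seed)
    n_gap = int(round(gap * epochs.fs))
    pieces = []
    events = []
    pos = 0
    stim_offset = epochs.time_index(0.0)
    scale = 0.05 * float(np.std(epochs.data)) if epochs.data.size else 1.0
    for j in range(epochs.n_trials):
        if n_gap:
            pieces.append(scale * rng.standard_normal((epochs.n_channels, n_gap)))
            pos += n_gap
        pieces.append(epochs.data[j])
        events.append((pos + stim_offset, str(epochs.labels.iloc[j]["condition"])))
        pos += epochs.n_samples
    data = np.concatenate(pieces, axis=1)
    return Recording(
        data=data,
        fs=epochs.fs,
        channel_labels=list(epochs.channel_labels),
        events=events,
    )
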