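"""Shared fixtures: small synthetic epoch sets and analytic ERD/ERS traces."""

import numpy as np
import pandas as pd
import pytest

from mirebound.containers import EpochSet, ERDSTrace
from mirebound.erders import band_power_timecourse, erders_timecourse
from mirebound.synthetic import default_profiles, generate_epochs


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def me_epochs(profiles):
    epochs, truth = generate_epochs(
        profiles["ME"], 40, ["Cz"], 250.0, (-1.0, 4.0), seed=11
    )
    return epochs, truth


@pytest.fixture(scope="session")
def small_epochs():
    """Deterministic noise-only epochs: 8 trials, 3 channels, 250 Hz."""
    rng = np.random.default_rng(7)
    n, ch, s = 8, 3, 1001
    data = rng.standard_normal((n, ch, s))
    labels = pd.DataFrame(
        {
            "condition": ["ME", "MI"] * (n // 2),
            "motion": ["M1"] * n,
            "hand": ["left", "right"] * (n // 2),
            "subject": ["S01"] * n,
        }
    )
    return EpochSet(
        data=data,
        fs=250.0,
        channel_labels=["Cz", "C3", "C4"],
        time_axis=-1.0 + np.arange(s) / 250.0,
        labels=labels,
    )


def gaussian_bump_trace(
    peaks,
    channels=("Cz",),
    fs=250.0,
    t0=-1.0,
    t1=4.0,
):
    """Analytic ERD/ERS trace: sum of Gaussian ERS bumps per channel.

    ``peaks`` maps channel -> list of (amplitude %, latency s, fwhm s).
    """
    t = np.arange(t0, t1 + 0.5 / fs, 1.0 / fs)
    values = np.zeros((len(channels), len(t)))
    for ci, ch in enumerate(channels):
        for amp, lat, fwhm in peaks.get(ch, []):
            values[ci] += amp * np.exp(-4 * np.log(2) * (t - lat) ** 2 / fwhm**2)
    return ERDSTrace(
        values=values,
        reference_power=np.ones(len(channels)),
        reference_interval=(-1.0, -0.1),
        band=(13.0, 40.0),
        time_axis=t,
        channel_labels=list(channels),
    )


def erds_of(epochs, **kwargs):
    return erders_timecourse(band_power_timecourse(epochs, **kwargs))
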