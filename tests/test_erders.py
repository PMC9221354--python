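"""ERD/ERS computation: the percentage identity, bootstrap, invariances."""

import numpy as np
import pytest

from mirebound.containers import BandPowerTimeCourse, EpochSet
from mirebound.erders import (
    band_power_timecourse,
    bootstrap_significance,
    condition_difference,
    erders_timecourse,
)
from mirebound.synthetic import ConditionProfile, generate_epochs

from conftest import erds_of


def bp_from_array(power, fs=250.0):
    power = np.atleast_2d(power)
    return BandPowerTimeCourse(
        power=power,
        band=(13.0, 40.0),
        n_trials=10,
        fs=fs,
        time_axis=-1.0 + np.arange(power.shape[1]) / fs,
        channel_labels=[f"C{i}" for i in range(power.shape[0])],
    )


class TestBandPower:
    def test_sinusoid_mean_square(self):
        fs = 250.0
        t = np.arange(-1.0, 4.0 + 0.5 / fs, 1 / fs)
        x = np.sin(2 * np.pi * 20.0 * t)
        data = np.tile(x, (4, 1, 1))
        epochs = EpochSet(
            data,
            fs,
            ["Cz"],
            t,
            labels=__import__("pandas").DataFrame(
                {"condition": ["ME"] * 4, "motion": "M1", "hand": "none", "subject": "S01"}
            ),
        )
        bp = band_power_timecourse(epochs, (13.0, 40.0))
        interior = slice(len(t) // 4, 3 * len(t) // 4)
        assert np.allclose(bp.power[0, interior], 0.5, rtol=0.10)

    def test_zero_epochs_zero_power(self, small_epochs):
        ep = EpochSet(
            small_epochs.data * 0,
            small_epochs.fs,
            list(small_epochs.channel_labels),
            small_epochs.time_axis,
            small_epochs.labels,
        )
        bp = band_power_timecourse(ep)
        assert np.all(bp.power == 0)

    def test_single_trial_error(self, small_epochs):
        ep = EpochSet(
            small_epochs.data[:1],
            small_epochs.fs,
            list(small_epochs.channel_labels),
            small_epochs.time_axis,
            small_epochs.labels.iloc[:1],
        )
        with pytest.raises(ValueError):
            band_power_timecourse(ep)


class TestErdersIdentity:
    def test_constant_power_is_zero_percent(self):
        bp = bp_from_array(np.full(1000, 2.0))
        trace = erders_timecourse(bp, (-1.0, -0.1))
        assert np.allclose(trace.values, 0.0)

    def test_doubling_gives_plus_100(self):
        power = np.full(1000, 1.0)
        power[600] = 2.0
        trace = erders_timecourse(bp_from_array(power), (-1.0, -0.1))
        assert trace.values[0, 600] == pytest.approx(100.0)

    def test_halving_gives_minus_50(self):
        power = np.full(1000, 1.0)
        power[600] = 0.5
        trace = erders_timecourse(bp_from_array(power), (-1.0, -0.1))
        assert trace.values[0, 600] == pytest.approx(-50.0)

    def test_reference_mean_is_zero(self, small_epochs):
        trace = erds_of(small_epochs)
        mask = (trace.time_axis >= -1.0 - 1e-9) & (trace.time_axis <= -0.1 + 1e-9)
        assert np.max(np.abs(trace.values[:, mask].mean(axis=1))) < 1e-9

    def test_degenerate_reference_error(self):
        power = np.zeros(1000)
        power[600] = 1.0
        with pytest.raises(ValueError, match="degenerate reference"):
            erders_timecourse(bp_from_array(power), (-1.0, -0.1))

    def test_scale_invariance(self, small_epochs):
        a = erds_of(small_epochs)
        scaled = EpochSet(
            small_epochs.data * 7.3,
            small_epochs.fs,
            list(small_epochs.channel_labels),
            small_epochs.time_axis,
            small_epochs.labels,
        )
        b = erds_of(scaled)
        assert np.allclose(a.values, b.values, atol=1e-8)

    def test_lower_bound_minus_100(self, small_epochs):
        trace = erds_of(small_epochs)
        assert np.all(trace.values >= -100.0)


class TestConditionDifference:
    def test_identical_traces_zero(self, small_epochs):
        t = erds_of(small_epochs)
        d = condition_difference(t, t)
        assert np.allclose(d.values, 0.0)

    def test_subtraction_and_antisymmetry(self, small_epochs):
        a = erds_of(small_epochs)
        b = erds_of(
            EpochSet(
                small_epochs.data[::-1].copy(),
                small_epochs.fs,
                list(small_epochs.channel_labels),
                small_epochs.time_axis,
                small_epochs.labels,
            )
        )
        d1 = condition_difference(a, b)
        d2 = condition_difference(b, a)
        assert np.allclose(d1.values, a.values - b.values)
        assert np.allclose(d1.values, -d2.values)

    def test_axis_mismatch_error(self, small_epochs):
        a = erds_of(small_epochs)
        b = erds_of(small_epochs.pick_channels(["Cz"]))
        with pytest.raises(ValueError):
            condition_difference(a, b)


class TestBootstrap:
    def test_deterministic_under_seed(self, me_epochs):
        epochs, _ = me_epochs
        m1 = bootstrap_significance(epochs, n_boot=150, seed=42)
        m2 = bootstrap_significance(epochs, n_boot=150, seed=42)
        assert np.array_equal(m1, m2)

    def test_false_positive_rate_on_null(self):
        """Unmodulated epochs: <= 10% of samples flagged at 95% confidence."""
        prof = ConditionProfile(rebound_amplitude=0.0, erd_depth=0.0)
        rates = []
        for seed in range(12):
            epochs, _ = generate_epochs(prof, 30, ["Cz"], 250, (-1, 4), seed=seed)
            mask = bootstrap_significance(epochs, n_boot=500, seed=seed)
            rates.append(mask.mean())
        assert np.mean(rates) <= 0.10

    def test_power_at_injected_peak(self, profiles):
        """The injected ME rebound peak is flagged significant in >= 90% of
        seeds."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            epochs, _ = generate_epochs(
                profiles["ME"], 40, ["Cz"], 250, (-1, 4), seed=seed
            )
            mask = bootstrap_significance(epochs, n_boot=300, seed=seed)
            i = epochs.time_index(profiles["ME"].rebound_latency)
            hits += bool(mask[0, i])
        assert hits >= 0.9 * n_seeds

    def test_too_few_trials_error(self, small_epochs):
        ep = EpochSet(
            small_epochs.data[:4],
            small_epochs.fs,
            list(small_epochs.channel_labels),
            small_epochs.time_axis,
            small_epochs.labels.iloc[:4],
        )
        with pytest.raises(ValueError):
            bootstrap_significance(ep, n_boot=200)


def test_peak_localization_improves_with_trials(profiles):
    """Median absolute latency error is non-increasing in the trial count."""
    prof = profiles["ME"]
    med_err = []
    for n in (10, 40, 160):
        errs = []
        for seed in range(12):
            epochs, _ = generate_epochs(prof, n, ["Cz"], 250, (-1, 4), seed=seed)
            trace = erds_of(epochs)
            i = np.argmax(trace.values[0])
            errs.append(abs(trace.time_axis[i] - prof.rebound_latency))
        med_err.append(np.median(errs))
    assert med_err[1] <= med_err[0] + 1e-12
    assert med_err[2] <= med_err[0] + 1e-12
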