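"""Feature families: statistics, wavelet, band power, sample entropy, CSP."""

import numpy as np
import pandas as pd
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

from mirebound.containers import EpochSet
from mirebound.features import (
    CSP,
    LEFT_RIGHT_BANDS,
    FeatureMatrix,
    SampEnConfig,
    assemble_features,
    band_power_features,
    csp_features,
    fit_csp,
    sample_entropy,
    sampen_features,
    statistical_features,
    wavelet_features,
)


def epochs_from_array(data, fs=250.0, channels=None, hand=None):
    data = np.asarray(data, float)
    n, ch, s = data.shape
    channels = channels or ["Cz", "C3", "C4"][:ch]
    labels = pd.DataFrame(
        {
            "condition": ["ME", "MI"] * (n // 2) + ["ME"] * (n % 2),
            "motion": ["M1"] * n,
            "hand": hand if hand is not None else ["none"] * n,
            "subject": ["S01"] * n,
        }
    )
    return EpochSet(data, fs, channels, np.arange(s) / fs, labels)


# ---------------------------------------------------------------------------
# statistical
# ---------------------------------------------------------------------------

class TestStatisticalFeatures:
    def test_hand_computed_differences(self):
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        ep = epochs_from_array(x[None, None, :], channels=["Cz"])
        fm = statistical_features(ep, ["Cz"])
        row = dict(zip(fm.feature_names, fm.values[0]))
        assert row["stat/Cz/mad1_raw"] == pytest.approx(1.0)
        assert row["stat/Cz/mad2_raw"] == pytest.approx(2.0)
        assert row["stat/Cz/mean"] == pytest.approx(0.4)
        assert row["stat/Cz/sd"] == pytest.approx(np.std(x))

    def test_standardized_features_affine_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 1, 200))
        a = statistical_features(epochs_from_array(x, channels=["Cz"]), ["Cz"])
        b = statistical_features(
            epochs_from_array(3.7 * x + 11.0, channels=["Cz"]), ["Cz"]
        )
        for name in ("mad1_std", "mad2_std"):
            ia = a.feature_names.index(f"stat/Cz/{name}")
            assert np.allclose(a.values[:, ia], b.values[:, ia])

    def test_constant_series_error(self):
        ep = epochs_from_array(np.ones((2, 1, 50)), channels=["Cz"])
        with pytest.raises(ValueError, match="standardize"):
            statistical_features(ep, ["Cz"])


# ---------------------------------------------------------------------------
# wavelet
# ---------------------------------------------------------------------------

class TestWaveletFeatures:
    def test_zero_epoch_all_zero(self):
        ep = epochs_from_array(np.zeros((2, 1, 256)), channels=["Cz"])
        fm = wavelet_features(ep, ["Cz"])
        assert np.allclose(fm.values, 0.0)

    def test_scaling_homogeneity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 1, 256))
        a = wavelet_features(epochs_from_array(x, channels=["Cz"]), ["Cz"])
        b = wavelet_features(epochs_from_array(3.0 * x, channels=["Cz"]), ["Cz"])
        names = a.feature_names
        rms, eng, ent = (names.index(f"wav/Cz/{s}") for s in ("rms", "eng", "ent"))
        assert np.allclose(b.values[:, rms], 3.0 * a.values[:, rms])
        assert np.allclose(b.values[:, eng], 9.0 * a.values[:, eng])
        assert np.allclose(b.values[:, ent], a.values[:, ent])

    def test_single_nonzero_coefficient_zero_entropy(self):
        # build a signal whose level-3 detail has a single dominant coeff
        coeffs = pywt.wavedec(np.zeros(256), "db4", level=3)
        coeffs[1] = np.zeros_like(coeffs[1])
        coeffs[1][10] = 5.0
        x = pywt.waverec(coeffs, "db4")
        ep = epochs_from_array(x[None, None, :], channels=["Cz"])
        fm = wavelet_features(ep, ["Cz"])
        ent = fm.values[0, fm.feature_names.index("wav/Cz/ent")]
        assert ent == pytest.approx(0.0, abs=1e-6)

    def test_too_short_epoch_error(self):
        ep = epochs_from_array(np.random.default_rng(0).standard_normal((2, 1, 32)),
                               channels=["Cz"])
        with pytest.raises(ValueError, match="too short"):
            wavelet_features(ep, ["Cz"])


# ---------------------------------------------------------------------------
# band power
# ---------------------------------------------------------------------------

class TestBandPowerFeatures:
    def test_pure_alpha_sinusoid(self):
        fs = 250.0
        t = np.arange(0, 4, 1 / fs)
        x = np.sin(2 * np.pi * 10.0 * t)
        ep = epochs_from_array(x[None, None, :], fs=fs, channels=["Cz"])
        fm = band_power_features(ep, ["Cz"])
        row = dict(zip(fm.feature_names, fm.values[0]))
        assert row["pow/Cz/alpha/rel"] >= 0.9
        assert row["pow/Cz/beta/rel"] <= 0.05

    def test_relative_powers_bounded(self):
        rng = np.random.default_rng(2)
        ep = epochs_from_array(rng.standard_normal((4, 1, 1000)), channels=["Cz"])
        fm = band_power_features(ep, ["Cz"])
        rel = [i for i, n in enumerate(fm.feature_names) if n.endswith("/rel")]
        vals = fm.values[:, rel]
        assert np.all(vals >= 0) and np.all(vals <= 1)
        assert np.all(vals.sum(axis=1) <= 1.0 + 1e-9)

    def test_white_noise_matches_bandwidth_ratio(self):
        """Relative band power of white noise approximates the bandwidth
        ratio of the band to the 1-60 Hz total (averaged over seeds)."""
        fs = 250.0
        rels = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ep = epochs_from_array(
                rng.standard_normal((1, 1, 5000)), fs=fs, channels=["Cz"]
            )
            fm = band_power_features(ep, ["Cz"])
            rels.append(fm.values[0, fm.feature_names.index("pow/Cz/beta/rel")])
        expected = (40.0 - 13.0) / (60.0 - 1.0)
        assert np.mean(rels) == pytest.approx(expected, rel=0.20)

    def test_band_above_nyquist_error(self):
        ep = epochs_from_array(np.zeros((2, 1, 500)), fs=100.0, channels=["Cz"])
        with pytest.raises(ValueError, match="Nyquist"):
            band_power_features(ep, ["Cz"], {"beta": (13.0, 60.0)})


# ---------------------------------------------------------------------------
# sample entropy
# ---------------------------------------------------------------------------

def sampen_bruteforce(x, m, r, mode):
    """Independent double-loop oracle for both counting conventions."""
    x = np.asarray(x, float)
    T = len(x)
    if np.ptp(x) == 0:
        return 0.0

    def count(mm, strict, n_templates, exclude_self):
        c = 0
        for i in range(n_templates):
            for j in range(n_templates):
                if exclude_self and i == j:
                    continue
                d = max(abs(x[i + k] - x[j + k]) for k in range(mm))
                c += (d < r) if strict else (d <= r)
        return c

    if mode == "literal":
        bm = count(m, True, T - m + 1, False) / (T - m + 1) ** 2
        bm1 = count(m + 1, True, T - m, False) / (T - m) ** 2
    else:
        n = T - m
        bm = count(m, False, n, True) / (n * (n - 1))
        bm1 = count(m + 1, False, n, True) / (n * (n - 1))
    if bm == 0 or bm1 == 0:
        return float("inf") if bm > 0 else 0.0
    return -np.log(bm1 / bm)


class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert sample_entropy(np.ones(30), SampEnConfig(m=2, r=0.5)) == 0.0
        assert sample_entropy(np.ones(30), SampEnConfig(m=2, mode="canonical")) == 0.0

    def test_periodic_series_matches_bruteforce_exactly(self):
        x = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 1], float)
        for mode in ("literal", "canonical"):
            got = sample_entropy(x, SampEnConfig(m=2, r=0.5, mode=mode))
            assert got == sampen_bruteforce(x, 2, 0.5, mode)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        length=st.integers(10, 60),
        mode=st.sampled_from(["literal", "canonical"]),
    )
    def test_matches_bruteforce_on_random_series(self, seed, length, mode):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(length)
        r = 0.5 * np.std(x)
        got = sample_entropy(x, SampEnConfig(m=2, r=r, mode=mode))
        want = sampen_bruteforce(x, 2, r, mode)
        assert got == want or (np.isinf(got) and np.isinf(want))

    def test_regular_signal_less_entropic_than_noise(self):
        hits = 0
        n_seeds = 100
        alternating = np.tile([0.0, 1.0], 50)
        alternating = (alternating - alternating.mean()) / alternating.std()
        cfg = SampEnConfig(m=2, r_factor=0.5)
        se_alt = sample_entropy(alternating, cfg)
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            noise = rng.standard_normal(100)
            hits += se_alt < sample_entropy(noise, cfg)
        assert hits >= 95

    def test_short_series_and_bad_r_errors(self):
        with pytest.raises(ValueError):
            sample_entropy(np.arange(3.0), SampEnConfig(m=2, r=0.5))
        with pytest.raises(ValueError):
            sample_entropy(np.arange(30.0), SampEnConfig(m=2, r=-1.0))


class TestSampenFeatures:
    def test_three_channels_give_six_columns(self, small_epochs):
        fm = sampen_features(small_epochs, ["Cz", "C3", "C4"])
        assert fm.values.shape[1] == 6
        assert all(n.startswith("sampen/") for n in fm.feature_names)

    def test_invariant_to_per_trial_rescaling(self, small_epochs):
        a = sampen_features(small_epochs, ["Cz"])
        scales = np.linspace(0.5, 4.0, small_epochs.n_trials)[:, None, None]
        scaled = EpochSet(
            small_epochs.data * scales,
            small_epochs.fs,
            list(small_epochs.channel_labels),
            small_epochs.time_axis,
            small_epochs.labels,
        )
        b = sampen_features(scaled, ["Cz"])
        raw = a.feature_names.index("sampen/Cz/raw")
        assert np.allclose(a.values[:, raw], b.values[:, raw], atol=1e-10)

    def test_constant_trial_zero_in_both_variants(self):
        data = np.ones((2, 1, 300))
        series = np.zeros((2, 1, 300))
        ep = epochs_from_array(data, channels=["Cz"])
        fm = sampen_features(ep, ["Cz"], erds_series=series)
        assert np.allclose(fm.values, 0.0)


# ---------------------------------------------------------------------------
# CSP
# ---------------------------------------------------------------------------

def two_class_epochs(seed=0, n=20, var_a=(4.0, 1.0), var_b=(1.0, 4.0), s=500):
    rng = np.random.default_rng(seed)
    xa = rng.standard_normal((n, 2, s)) * np.sqrt(np.array(var_a))[None, :, None]
    xb = rng.standard_normal((n, 2, s)) * np.sqrt(np.array(var_b))[None, :, None]
    X = np.concatenate([xa, xb])
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestCSP:
    def test_identical_covariance_eigenvalues_half(self):
        X, y = two_class_epochs(seed=1, var_a=(1.0, 1.0), var_b=(1.0, 1.0), n=40)
        model = CSP().fit(X, y)
        assert np.allclose(model.eigenvalues_, 0.5, atol=0.05)

    def test_discriminative_direction_found(self):
        X, y = two_class_epochs(seed=2)
        model = CSP().fit(X, y)
        top = model.filters_[0]
        va = np.mean([(top @ t) @ (top @ t) for t in X[:20]])
        vb = np.mean([(top @ t) @ (top @ t) for t in X[20:]])
        assert max(va, vb) / min(va, vb) >= 4.0

    def test_simultaneous_diagonalization(self):
        X, y = two_class_epochs(seed=3)
        model = CSP().fit(X, y)
        ca = CSP._class_cov(X[:20])
        cb = CSP._class_cov(X[20:])
        for c in (ca, cb):
            proj = model.filters_ @ c @ model.filters_.T
            off = proj - np.diag(np.diag(proj))
            assert np.max(np.abs(off)) <= 1e-6 * np.max(np.abs(np.diag(proj)))

    def test_features_sum_to_one(self):
        X, y = two_class_epochs(seed=4)
        model = CSP().fit(X, y)
        feats = model.transform(X)
        assert np.allclose(feats.sum(axis=1), 1.0)

    def test_toy_trial_log_variance_oracle(self):
        """Identity-like filters on a 2-channel toy trial reproduce the
        hand-computed normalized log-variance ratio."""
        X, y = two_class_epochs(seed=5)
        model = CSP().fit(X, y)
        model.filters_ = np.eye(2)
        model.selected_ = np.array([0, 1])
        trial = np.array([[1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0],
                          [10.0, -10.0, 10.0, -10.0, 10.0, -10.0, 10.0, -10.0]])
        f = csp_features(model, trial)
        lv = np.log([trial[0].var(), trial[1].var()])
        assert np.allclose(f, lv / lv.sum())
        assert f.sum() == pytest.approx(1.0)

    def test_class_swap_symmetry(self):
        X, y = two_class_epochs(seed=6)
        m1 = CSP().fit(X, y)
        y_swapped = np.where(y == "a", "b", "a")
        m2 = CSP().fit(X, y_swapped)
        assert np.allclose(np.sort(m2.eigenvalues_), np.sort(1.0 - m1.eigenvalues_),
                           atol=1e-10)
        f1 = m1.transform(X)
        f2 = m2.transform(X)
        assert np.allclose(np.sort(f1, axis=1), np.sort(f2, axis=1), atol=1e-8)

    def test_agrees_with_mne_csp_on_variance_ratio(self):
        """Cross-check against the MNE implementation: the most
        discriminative filter captures the same class-variance ratio."""
        from mne.decoding import CSP as MneCSP

        X, y = two_class_epochs(seed=7)
        ours = CSP().fit(X, np.asarray(y))
        mne_csp = MneCSP(n_components=2, transform_into="csp_space", norm_trace=True)
        mne_csp.fit(X.copy(), (y == "b").astype(int))

        def ratio(w):
            va = np.mean([np.var(w @ t) for t in X[:20]])
            vb = np.mean([np.var(w @ t) for t in X[20:]])
            return max(va / vb, vb / va)

        r_ours = max(ratio(ours.filters_[0]), ratio(ours.filters_[-1]))
        r_mne = max(ratio(mne_csp.filters_[0]), ratio(mne_csp.filters_[1]))
        assert r_ours == pytest.approx(r_mne, rel=0.05)

    def test_rank_deficiency_error(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal((10, 1, 100))
        X = np.concatenate([base, base], axis=1)  # duplicated channel
        y = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError, match="rank"):
            CSP().fit(X, y)

    def test_fit_csp_wrapper(self, small_epochs):
        a = small_epochs.pick_channels(["Cz", "C3"])
        model = fit_csp(a, a)
        assert model.filters_.shape == (2, 2)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

class TestAssembleFeatures:
    def test_me_vs_mi_has_13_columns(self, small_epochs):
        fm = assemble_features(small_epochs, "me_vs_mi")
        assert fm.n_features == 13
        assert set(fm.labels) == {"ME", "MI"}

    def test_left_vs_right_has_59_columns(self, small_epochs):
        fm = assemble_features(small_epochs, "left_vs_right")
        assert fm.n_features == 59
        assert set(fm.labels) == {"left", "right"}

    def test_left_right_family_block_sizes(self, small_epochs):
        fm = assemble_features(small_epochs, "left_vs_right")
        fams = {}
        for n in fm.feature_names:
            fams[n.split("/")[0]] = fams.get(n.split("/")[0], 0) + 1
        assert fams == {"stat": 18, "wav": 9, "pow": 24, "sampen": 6, "csp": 2}

    def test_names_unique_and_stable(self, small_epochs):
        a = assemble_features(small_epochs, "me_vs_mi")
        b = assemble_features(small_epochs, "me_vs_mi")
        assert a.feature_names == b.feature_names
        assert len(set(a.feature_names)) == len(a.feature_names)
        assert np.array_equal(a.values, b.values)

    def test_missing_channel_error(self, small_epochs):
        ep = small_epochs.pick_channels(["C3", "C4"])
        with pytest.raises(ValueError, match="Cz"):
            assemble_features(ep, "me_vs_mi")

    def test_feature_matrix_validation(self):
        with pytest.raises(ValueError, match="unique"):
            FeatureMatrix(np.zeros((2, 2)), ["a", "a"], np.array(["x", "y"]))
        with pytest.raises(ValueError, match="finite"):
            FeatureMatrix(np.array([[np.nan, 0.0]]), ["a", "b"], np.array(["x"]))
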