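"""Five feature families for motor-imagery classification.

Families: simple statistics of the raw/standardized signal, db4 wavelet
level-3 detail features, Welch band power (absolute and relative), sample
entropy of raw and single-trial ERD/ERS series, and common spatial patterns.
Two ready-made configurations assemble the matrices used by the two
classification tasks: 13 columns (Cz only) for ME vs MI and 59 columns
(Cz/C3/C4) for left vs right hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import linalg, signal
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import EpochSet
from .erders import BETA_BAND, REFERENCE_INTERVAL, single_trial_erders

__all__ = [
    "FeatureMatrix",
    "SampEnConfig",
    "statistical_features",
    "wavelet_features",
    "band_power_features",
    "sample_entropy",
    "sampen_features",
    "CSP",
    "fit_csp",
    "csp_features",
    "assemble_features",
    "ME_MI_BANDS",
    "LEFT_RIGHT_BANDS",
]

#: alpha/beta rhythms of the ME-vs-MI configuration
ME_MI_BANDS = {"alpha": (8.0, 12.0), "beta": (13.0, 40.0)}
#: left-vs-right additionally splits beta into low/high sub-bands so that the
#: power family contributes 8 columns per channel
LEFT_RIGHT_BANDS = {
    "alpha": (8.0, 12.0),
    "beta": (13.0, 40.0),
    "beta_low": (13.0, 20.0),
    "beta_high": (20.0, 40.0),
}
TOTAL_BAND = (1.0, 60.0)


@dataclass
class FeatureMatrix:
    """Trials x named-features table with per-trial class labels."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trials x features)")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must match rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        return df

    @staticmethod
    def hstack(blocks: list["FeatureMatrix"]) -> "FeatureMatrix":
        names = [n for b in blocks for n in b.feature_names]
        labels = blocks[0].labels
        for b in blocks[1:]:
            if not np.array_equal(b.labels, labels):
                raise ValueError("blocks carry different labels")
        return FeatureMatrix(
            values=np.hstack([b.values for b in blocks]),
            feature_names=names,
            labels=labels,
        )


# ---------------------------------------------------------------------------
# statistical features
# ---------------------------------------------------------------------------

def statistical_features(epochs: EpochSet, channels: list[str]) -> FeatureMatrix:
    """Six statistics per channel: mean, SD, and mean absolute first/second
    differences of the raw and of the standardized signal.

    The standardized-signal statistics are invariant to affine rescaling of
    the input.  A zero-variance epoch cannot be standardized and raises.
    """
    if epochs.n_samples < 3:
        raise ValueError("need >= 3 samples per epoch")
    idx = [epochs.channel_index(c) for c in channels]
    rows = []
    for trial in epochs.data:
        feats = []
        for i in idx:
            x = trial[i]
            sd = x.std()
            if sd == 0:
                raise ValueError("cannot standardize a zero-variance epoch")
            z = (x - x.mean()) / sd
            feats += [
                x.mean(),
                sd,
                np.abs(np.diff(x)).mean(),
                np.abs(np.diff(x, n=2)).mean(),
                np.abs(np.diff(z)).mean(),
                np.abs(np.diff(z, n=2)).mean(),
            ]
        rows.append(feats)
    names = [
        f"stat/{c}/{s}"
        for c in channels
        for s in ("mean", "sd", "mad1_raw", "mad2_raw", "mad1_std", "mad2_std")
    ]
    return FeatureMatrix(np.array(rows), names, epochs.labels["condition"].to_numpy())


# ---------------------------------------------------------------------------
# wavelet features
# ---------------------------------------------------------------------------

def _wavelet_stats(x: np.ndarray) -> tuple[float, float, float]:
    coeffs = pywt.wavedec(x, "db4", level=3)
    d3 = coeffs[1]  # detail coefficients at level 3
    e = d3**2
    eng = float(e.sum())
    rms = float(np.sqrt(e.mean()))
    if eng == 0:
        return 0.0, 0.0, 0.0
    p = e / eng
    nz = p > 0
    ent = float(-(p[nz] * np.log(p[nz])).sum())
    return rms, eng, ent


def wavelet_features(epochs: EpochSet, channels: list[str]) -> FeatureMatrix:
    """db4 level-3 detail coefficients: RMS, energy and Shannon entropy."""
    if pywt.dwt_max_level(epochs.n_samples, "db4") < 3:
        raise ValueError("epoch too short for a 3-level db4 decomposition")
    idx = [epochs.channel_index(c) for c in channels]
    rows = [
        [v for i in idx for v in _wavelet_stats(trial[i])] for trial in epochs.data
    ]
    names = [f"wav/{c}/{s}" for c in channels for s in ("rms", "eng", "ent")]
    return FeatureMatrix(np.array(rows), names, epochs.labels["condition"].to_numpy())


# ---------------------------------------------------------------------------
# Welch band power features
# ---------------------------------------------------------------------------

def _welch_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(len(x), int(round(fs)))  # 1 s Hamming segments, 50% overlap
    return signal.welch(x, fs=fs, window="hamming", nperseg=nperseg)


def _band_integral(f: np.ndarray, p: np.ndarray, band: tuple[float, float]) -> float:
    m = (f >= band[0]) & (f <= band[1])
    if m.sum() < 2:
        return float(p[m].sum() * (f[1] - f[0])) if m.any() else 0.0
    return float(np.trapezoid(p[m], f[m]))


def band_power_features(
    epochs: EpochSet,
    channels: list[str],
    bands: dict[str, tuple[float, float]] = ME_MI_BANDS,
) -> FeatureMatrix:
    """Welch-PSD band power, absolute and relative to total power in 1-60 Hz."""
    for name, (lo, hi) in bands.items():
        if hi >= epochs.fs / 2.0:
            raise ValueError(f"band {name!r} above Nyquist")
    idx = [epochs.channel_index(c) for c in channels]
    total_band = (TOTAL_BAND[0], min(TOTAL_BAND[1], epochs.fs / 2.0))
    rows = []
    for trial in epochs.data:
        feats = []
        for i in idx:
            f, p = _welch_psd(trial[i], epochs.fs)
            total = _band_integral(f, p, total_band)
            for band in bands.values():
                absolute = _band_integral(f, p, band)
                feats += [absolute, absolute / total if total > 0 else 0.0]
        rows.append(feats)
    names = [
        f"pow/{c}/{b}/{q}" for c in channels for b in bands for q in ("abs", "rel")
    ]
    return FeatureMatrix(np.array(rows), names, epochs.labels["condition"].to_numpy())


# ---------------------------------------------------------------------------
# sample entropy
# ---------------------------------------------------------------------------

@dataclass
class SampEnConfig:
    """Sample-entropy parameters.

    ``mode='literal'`` follows the printed definition: templates of length m
    are X_i = (x_i, ..., x_{i+m-1}) for i = 1..T-m+1, matches are counted with
    a strict Chebyshev distance ``< r`` *including* the self-match, and
    B_m(r) uses a (T-m+1)^2 denominator (correspondingly (T-m)^2 at length
    m+1).  ``mode='canonical'`` uses the conventional estimator: both template
    lengths indexed to T-m, self-matches excluded, distance ``<= r``,
    denominator (T-m)(T-m-1).
    """

    m: int = 2
    r: float | None = None
    r_mode: str = "multiple_of_sd"
    r_factor: float = 1.0
    mode: str = "literal"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be > 0")
        if self.mode not in ("literal", "canonical"):
            raise ValueError("mode must be 'literal' or 'canonical'")


def _template_distances(x: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Chebyshev distances between templates of length m and m+1.

    Built incrementally from the scalar distance matrix: the distance between
    length-(k+1) templates is the maximum of the length-k distance and the
    shifted scalar distance, so the m and m+1 matrices come from one O(T^2)
    pass without materializing the template tensor.
    """
    d1 = np.abs(x[:, None] - x[None, :])
    d = d1
    for k in range(1, m):
        d = np.maximum(d[:-1, :-1], d1[k:, k:])
    d_m1 = np.maximum(d[:-1, :-1], d1[m:, m:])
    return d, d_m1


def sample_entropy(series: np.ndarray, cfg: SampEnConfig | None = None) -> float:
    """Sample entropy of a 1-D series.

    Returns 0 for a constant series and ``+inf`` when no template matches
    survive at length m+1 (callers may impute, see :func:`sampen_features`).
    """
    cfg = cfg or SampEnConfig()
    x = np.asarray(series, dtype=float).ravel()
    T = len(x)
    if T < cfg.m + 2:
        raise ValueError("series too short for the requested template length")
    if np.ptp(x) == 0:
        return 0.0
    r = cfg.r
    if r is None:
        if cfg.r_mode != "multiple_of_sd":
            raise ValueError("r not given and r_mode unknown")
        r = cfg.r_factor * float(np.std(x))
    if r <= 0:
        raise ValueError("similarity tolerance r must be > 0")

    m = cfg.m
    d_m, d_m1 = _template_distances(x, m)
    if cfg.mode == "literal":
        # T-m+1 templates at length m, T-m at length m+1; strict < with
        # self-matches included, squared-count denominators
        bm = np.count_nonzero(d_m < r) / (T - m + 1) ** 2
        bm1 = np.count_nonzero(d_m1 < r) / (T - m) ** 2
    else:
        # both lengths indexed to T-m templates, self-matches excluded
        denom = (T - m) * (T - m - 1)
        n = T - m
        bm = (np.count_nonzero(d_m[:n, :n] <= r) - n) / denom
        bm1 = (np.count_nonzero(d_m1 <= r) - n) / denom
    if bm == 0 or bm1 == 0:
        return float("inf") if bm > 0 else 0.0
    return float(-np.log(bm1 / bm))


def _sampen_cap(T: int, m: int, mode: str) -> float:
    """Finite stand-in for an infinite sample entropy (no m+1 matches)."""
    if mode == "literal":
        return float(-np.log(1.0 / (T - m) ** 2))
    return float(-np.log(1.0 / ((T - m) * (T - m - 1))))


def sampen_features(
    epochs: EpochSet,
    channels: list[str] = ("Cz", "C3", "C4"),
    band: tuple[float, float] = BETA_BAND,
    reference_interval: tuple[float, float] = REFERENCE_INTERVAL,
    mode: str = "literal",
    erds_series: np.ndarray | None = None,
) -> FeatureMatrix:
    """Sample entropy of raw epochs (r = 1.0 SD) and of per-trial ERD/ERS
    series (r = 0.1 SD), m = 2, on the requested channels.

    ``erds_series`` may be supplied precomputed (trials x channels x samples,
    matching the epoch channel order); otherwise it is derived from the
    epochs.  Infinite values (no length-3 template matches) are imputed with
    the largest finite value the estimator can produce at that series length.
    """
    channels = list(channels)
    if erds_series is None:
        erds_series = single_trial_erders(epochs, band, reference_interval)
    idx = [epochs.channel_index(c) for c in channels]
    cfg_raw = SampEnConfig(m=2, r_factor=1.0, mode=mode)
    cfg_erds = SampEnConfig(m=2, r_factor=0.1, mode=mode)
    rows = []
    for j in range(epochs.n_trials):
        feats = []
        for i in idx:
            for cfg, src in ((cfg_raw, epochs.data[j, i]), (cfg_erds, erds_series[j, i])):
                v = sample_entropy(src, cfg)
                if np.isinf(v):
                    v = _sampen_cap(len(src), cfg.m, mode)
                feats.append(v)
        rows.append(feats)
    names = [f"sampen/{c}/{s}" for c in channels for s in ("raw", "erds")]
    return FeatureMatrix(np.array(rows), names, epochs.labels["condition"].to_numpy())


# ---------------------------------------------------------------------------
# common spatial patterns
# ---------------------------------------------------------------------------

class CSP(BaseEstimator, TransformerMixin):
    """Common spatial patterns for two-class oscillatory EEG.

    Fits spatial filters that jointly diagonalize the two class-average
    (trace-normalized) covariance matrices, sorted by the generalized
    eigenvalue (the share of class-A variance captured).  ``transform``
    returns the two normalized log-variance features of the first and last
    filter for each trial.

    Parameters
    ----------
    n_components : int
        Number of filters retained for features (2: most discriminative pair).
    feature_mode : {'literal', 'conventional'}
        'literal' normalizes each log variance by the sum of the selected log
        variances (so the two features always sum to 1); 'conventional' is
        the usual log of the normalized variance.
    """

    def __init__(self, n_components: int = 2, feature_mode: str = "literal"):
        self.n_components = n_components
        self.feature_mode = feature_mode

    @staticmethod
    def _class_cov(x: np.ndarray) -> np.ndarray:
        covs = []
        for trial in x:
            c = trial @ trial.T
            tr = np.trace(c)
            if tr <= 0:
                raise ValueError("zero-variance trial")
            covs.append(c / tr)
        return np.mean(covs, axis=0)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CSP":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be trials x channels x samples")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("CSP requires exactly two classes")
        xa, xb = X[y == classes[0]], X[y == classes[1]]
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError("need >= 2 trials per class")
        ca, cb = self._class_cov(xa), self._class_cov(xb)
        n_ch = ca.shape[0]
        comp = ca + cb
        if np.linalg.matrix_rank(comp) < n_ch:
            raise ValueError(
                "rank-deficient composite covariance; reduce the channel count "
                f"(have {n_ch} channels)"
            )
        evals, evecs = linalg.eigh(ca, comp)
        order = np.argsort(evals)[::-1]
        self.eigenvalues_ = np.clip(evals[order], 0.0, 1.0)
        self.filters_ = evecs[:, order].T  # filters x channels
        self.patterns_ = linalg.pinv(self.filters_)
        self.classes_ = classes
        k = self.n_components
        self.selected_ = np.array([*range(k // 2), *range(n_ch - (k - k // 2), n_ch)])
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "filters_"):
            raise ValueError("CSP is not fitted")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        if X.shape[1] != self.filters_.shape[1]:
            raise ValueError("trial channel count does not match the fitted model")
        W = self.filters_[self.selected_]
        proj = np.einsum("fc,tcs->tfs", W, X)
        var = proj.var(axis=-1)
        if np.any(var <= 0):
            raise ValueError("zero variance on a CSP projection")
        logv = np.log(var)
        if self.feature_mode == "literal":
            denom = logv.sum(axis=1, keepdims=True)
            if np.any(denom == 0):
                raise ValueError("sum of log variances is zero; cannot normalize")
            feats = logv / denom
        else:
            feats = np.log(var / var.sum(axis=1, keepdims=True))
        return feats[0] if single else feats


def fit_csp(epochs_a: EpochSet, epochs_b: EpochSet, **kwargs) -> CSP:
    """Fit :class:`CSP` on two single-condition epoch sets."""
    if epochs_a.channel_labels != epochs_b.channel_labels:
        raise ValueError("epoch sets carry different channels")
    X = np.concatenate([epochs_a.data, epochs_b.data])
    y = np.array([0] * epochs_a.n_trials + [1] * epochs_b.n_trials)
    return CSP(**kwargs).fit(X, y)


def csp_features(model: CSP, epoch: np.ndarray) -> np.ndarray:
    """Two-component CSP feature vector of a single trial."""
    return model.transform(np.asarray(epoch, dtype=float))


# ---------------------------------------------------------------------------
# task-level assembly
# ---------------------------------------------------------------------------

def assemble_features(
    epochs: EpochSet,
    task: str,
    *,
    band: tuple[float, float] = BETA_BAND,
    reference_interval: tuple[float, float] = REFERENCE_INTERVAL,
    label_column: str | None = None,
    sampen_mode: str = "literal",
    erds_series: np.ndarray | None = None,
) -> FeatureMatrix:
    """Assemble the per-task feature matrix.

    ``task='me_vs_mi'``: 13 columns on Cz (6 statistical + 3 wavelet +
    4 alpha/beta power).  ``task='left_vs_right'``: 59 columns over Cz, C3,
    C4 (18 statistical + 9 wavelet + 24 power over four sub-bands + 6 sample
    entropy + 2 CSP).  Column order is fixed: statistical, wavelet, power,
    then (left_vs_right only) sample entropy and CSP.
    """
    if task == "me_vs_mi":
        channels = ["Cz"]
        label_column = label_column or "condition"
    elif task == "left_vs_right":
        channels = ["Cz", "C3", "C4"]
        label_column = label_column or "hand"
    else:
        raise ValueError("task must be 'me_vs_mi' or 'left_vs_right'")
    for c in channels:
        if c not in epochs.channel_labels:
            raise ValueError(f"required channel {c!r} missing from epochs")
    labels = epochs.labels[label_column].to_numpy()

    blocks = [
        statistical_features(epochs, channels),
        wavelet_features(epochs, channels),
        band_power_features(
            epochs, channels, ME_MI_BANDS if task == "me_vs_mi" else LEFT_RIGHT_BANDS
        ),
    ]
    if task == "left_vs_right":
        blocks.append(
            sampen_features(
                epochs,
                channels,
                band,
                reference_interval,
                mode=sampen_mode,
                erds_series=erds_series,
            )
        )
        csp = CSP(n_components=2).fit(epochs.data, labels)
        csp_block = FeatureMatrix(
            values=csp.transform(epochs.data),
            feature_names=["csp/f1", "csp/f2"],
            labels=blocks[0].labels,
        )
        blocks.append(csp_block)
    fm = FeatureMatrix.hstack(blocks)
    return FeatureMatrix(fm.values, fm.feature_names, labels)
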