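"""Sparse logistic regression (SLR) feature selection.

Four variants of sparse binary logistic regression, all yielding automatic
feature selection:

* ``slr-lap`` — automatic relevance determination (ARD): each weight has its
  own Gaussian prior precision ("relevance"); the posterior is approximated
  by a Laplace (Newton/MAP + local Gaussian) step and the precisions are
  re-estimated with the MacKay fixed-point update.  Features whose precision
  diverges are pruned.
* ``slr-var`` — the same ARD model with a variational posterior based on the
  Jaakkola-Jordan bound of the logistic likelihood instead of the Laplace
  approximation.
* ``l1-slr-lap`` — MAP estimation under a Laplace (double-exponential) prior,
  i.e. L1-penalized logistic regression, solved globally (liblinear); the
  penalty strength is chosen by internal stratified cross-validation with a
  one-standard-error rule favouring the sparser model.
* ``l1-slr-comp`` — the same L1 objective solved by component-wise
  (cyclic coordinate-descent) updates with a per-coordinate quadratic bound.

Features are standardized internally; the intercept is never penalized and
never pruned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold

__all__ = ["SLRFit", "SparseLogisticRegression", "fit_slr", "VARIANTS", "selected_at"]

VARIANTS = ("slr-lap", "slr-var", "l1-slr-lap", "l1-slr-comp")

#: canonical names as printed in comparison tables
VARIANT_LABELS = {
    "slr-lap": "SLR-LAP",
    "slr-var": "SLR-VAR",
    "l1-slr-lap": "L1-SLR-LAP",
    "l1-slr-comp": "L1-SLR-COMP",
}

_ALPHA_MAX = 1e12
_WEIGHT_EPS = 1e-6


@dataclass
class SLRFit:
    """Result of one sparse-logistic-regression fit."""

    variant: str
    weights: np.ndarray  # per-feature coefficients (standardized space)
    intercept: float
    relevance: np.ndarray | None  # ARD precisions, None for L1 variants
    selected: np.ndarray  # indices of surviving features
    iterations: int
    converged: bool
    feature_names: list[str] | None = None


def selected_at(fit: SLRFit, prune_threshold: float) -> np.ndarray:
    """Indices surviving at a (possibly stricter) ARD pruning threshold."""
    if fit.relevance is None:
        raise ValueError("relevance-based selection needs an ARD fit")
    return np.where(
        (fit.relevance < prune_threshold) & (np.abs(fit.weights) > _WEIGHT_EPS)
    )[0]


def _log_loss(w: np.ndarray, D: np.ndarray, y01: np.ndarray) -> float:
    z = D @ w
    return float(np.sum(np.logaddexp(0.0, z) - y01 * z))


class SparseLogisticRegression(ClassifierMixin, BaseEstimator):
    """Sklearn-style estimator for the four SLR variants.

    Parameters
    ----------
    variant : {'slr-lap', 'slr-var', 'l1-slr-lap', 'l1-slr-comp'}
    max_iter : int
        Outer iterations (relevance updates for ARD; CD cycles for COMP).
    tol : float
        Relative convergence tolerance on the objective.
    prune_threshold : float
        ARD precision above which a feature counts as pruned.
    cs : array-like or None
        Inverse-penalty grid for the L1 variants (internal CV); defaults to a
        13-point log grid.
    cv : int
        Folds of the internal CV choosing the L1 penalty.
    random_state : int
        Seeds the internal CV splits.

    Attributes (after fit)
    ----------------------
    coef_, intercept_ : weights in standardized feature space
    relevance_ : ARD precisions (None for L1 variants)
    selected_ : indices of surviving features
    n_iter_, converged_
    """

    def __init__(
        self,
        variant: str = "l1-slr-lap",
        max_iter: int = 500,
        tol: float = 1e-5,
        prune_threshold: float = 1e8,
        cs=None,
        cv: int = 5,
        evidence_bf: float = 3.0,
        random_state: int = 0,
    ):
        self.variant = variant
        self.max_iter = max_iter
        self.tol = tol
        self.prune_threshold = prune_threshold
        self.cs = cs
        self.cv = cv
        self.evidence_bf = evidence_bf
        self.random_state = random_state

    # -- shared helpers -----------------------------------------------------

    def _encode(self, y):
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("SLR requires exactly two classes")
        return classes, (y == classes[1]).astype(float)

    def _standardize(self, X):
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        if np.any(scale == 0):
            raise ValueError("constant feature column after standardization")
        return (X - mean) / scale, mean, scale

    # -- ARD variants -------------------------------------------------------

    def _map_newton(self, D, y01, alpha_full, w0):
        """Penalized-likelihood MAP via Newton iterations; returns w, Hessian."""
        w = w0.copy()
        A = np.diag(alpha_full)
        for _ in range(100):
            p = expit(D @ w)
            g = D.T @ (p - y01) + alpha_full * w
            s = np.clip(p * (1 - p), 1e-10, None)
            H = (D * s[:, None]).T @ D + A
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            w_new = w - step
            if np.max(np.abs(w_new - w)) < 1e-9:
                w = w_new
                break
            w = w_new
        p = expit(D @ w)
        s = np.clip(p * (1 - p), 1e-10, None)
        H = (D * s[:, None]).T @ D + np.diag(alpha_full)
        return w, H

    def _fit_ard(self, Xs, y01):
        """ARD outer loop shared by the Laplace and variational variants.

        Each iteration refits the Gaussian posterior approximation on the
        active set, then re-estimates the per-feature relevance precisions
        via their marginal-likelihood sparsity/quality factors
        (``s_j``/``q_j``): a feature whose quality no longer exceeds its
        sparsity (``q^2 <= s``) has its evidence maximized at infinite
        precision and is pruned outright; the others get the evidence
        fixed-point ``alpha = s^2 / (q^2 - s)``.
        """
        n, p = Xs.shape
        D = np.hstack([Xs, np.ones((n, 1))])
        active = np.arange(p)
        alpha = np.ones(p)
        alpha_intercept = 1e-8  # effectively flat prior on the intercept
        w_full = np.zeros(p + 1)
        converged = False
        it = 0
        s_f = q_f = np.zeros(0)
        for it in range(1, self.max_iter + 1):
            cols = np.append(active, p)
            alpha_a = np.append(alpha[active], alpha_intercept)
            w_a, Sigma, S_vec, Q_vec = self._posterior_sq(
                D[:, cols], y01, alpha_a, w_full[cols]
            )
            w_full[:] = 0.0
            w_full[cols] = w_a
            alpha_old = alpha[active].copy()
            a = alpha[active]
            S_f, Q_f = S_vec[:-1], Q_vec[:-1]
            denom = a - S_f
            ok = denom > 1e-10
            s_f = np.where(ok, a * S_f / np.where(ok, denom, 1.0), S_f)
            q_f = np.where(ok, a * Q_f / np.where(ok, denom, 1.0), Q_f)
            rel = q_f**2 - s_f
            with np.errstate(divide="ignore", invalid="ignore"):
                alpha_new = np.where(rel > 0, s_f**2 / np.where(rel > 0, rel, 1.0), np.inf)
            alpha[active] = np.minimum(alpha_new, _ALPHA_MAX)
            keep = (rel > 0) & (alpha[active] < self.prune_threshold)
            w_full[active[~keep]] = 0.0
            if keep.any():
                delta = np.max(
                    np.abs(np.log(alpha[active][keep]) - np.log(alpha_old[keep]))
                )
            else:
                delta = 0.0
            pruned_any = (~keep).any()
            active, s_f, q_f = active[keep], s_f[keep], q_f[keep]
            if len(active) == 0 or (not pruned_any and delta < max(self.tol, 1e-4)):
                converged = True
                break
        if np.max(np.abs(w_full)) > 1e3:
            warnings.warn("SLR weights capped; data may be separable")
            w_full = np.clip(w_full, -1e3, 1e3)
            converged = False
        # Final relevance decision: a surviving feature must carry moderate
        # evidence.  Its marginal-likelihood gain over pruning it is
        # 0.5 (z^2 - 1 - ln z^2) with z^2 = q^2/s; require a Bayes factor of
        # at least `evidence_bf` so that weights merely hovering at one
        # posterior SD do not count as selected.
        if len(active):
            with np.errstate(divide="ignore", invalid="ignore"):
                z2 = np.where(s_f > 0, q_f**2 / np.where(s_f > 0, s_f, 1.0), np.inf)
            gain = 0.5 * (z2 - 1.0 - np.log(z2))
            relevant = gain > np.log(self.evidence_bf)
            selected = active[relevant & (np.abs(w_full[active]) > _WEIGHT_EPS)]
        else:
            selected = active
        return w_full[:-1], w_full[-1], alpha, selected, it, converged

    def _posterior_sq(self, Da, y01, alpha_a, w0):
        """Gaussian posterior plus per-feature sparsity/quality statistics."""
        if self.variant == "slr-lap":
            w_a, H = self._map_newton(Da, y01, alpha_a, w0)
            Sigma = np.linalg.inv(H)
            prob = expit(Da @ w_a)
            bvec = np.clip(prob * (1.0 - prob), 1e-10, None)
            G = (Da * bvec[:, None]).T @ Da
            # G w + grad of loglik = Phi' B t_hat (working response)
            b = G @ w_a + Da.T @ (y01 - prob)
        else:  # slr-var: Jaakkola-Jordan bound
            w_a, Sigma, lam = self._var_posterior(Da, y01, alpha_a, w0)
            G = 2.0 * (Da * lam[:, None]).T @ Da
            b = Da.T @ (y01 - 0.5)
        GS = G @ Sigma
        S_vec = np.diag(G) - np.einsum("ij,ji->i", GS, G)
        Q_vec = b - GS @ b
        return w_a, Sigma, S_vec, Q_vec

    def _var_posterior(self, D, y01, alpha_full, w0):
        """Variational Gaussian posterior under the Jaakkola-Jordan bound."""
        n, d = D.shape
        xi = np.ones(n)
        t = y01 - 0.5
        m = w0.copy()
        A = np.diag(alpha_full)
        S = None
        lam = np.full(n, 0.125)
        for _ in range(50):
            lam = np.where(xi > 1e-8, np.tanh(xi / 2.0) / (4.0 * xi), 0.125)
            S_inv = A + 2.0 * (D * lam[:, None]).T @ D
            S = np.linalg.inv(S_inv)
            m_new = S @ (D.T @ t)
            xi_new = np.sqrt(np.einsum("nd,de,ne->n", D, S + np.outer(m_new, m_new), D))
            if np.max(np.abs(m_new - m)) < 1e-9:
                m = m_new
                break
            m, xi = m_new, xi_new
        return m, S, lam

    # -- L1 variants --------------------------------------------------------

    def _l1_path_fit(self, Xs, y01, C):
        if self.variant == "l1-slr-lap":
            clf = LogisticRegression(
                l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, tol=1e-8,
                random_state=0,
            )
            clf.fit(Xs, y01)
            return clf.coef_.ravel().copy(), float(clf.intercept_[0]), 1, True
        return self._l1_coordinate_descent(Xs, y01, C)

    def _l1_coordinate_descent(self, Xs, y01, C):
        """Cyclic coordinate descent for L1 logistic MAP.

        Objective: sum_i log(1+exp(-z)) - y*z scaled by C plus ||w||_1, the
        same parametrization as liblinear, so the two L1 variants share a
        penalty grid.  Each coordinate uses the 1/4 curvature bound of the
        logistic loss, giving a guaranteed-descent soft-threshold step.
        """
        n, p = Xs.shape
        w = np.zeros(p)
        b = 0.0
        L = 0.25 * C * np.sum(Xs**2, axis=0)  # per-coordinate curvature bound
        Lb = 0.25 * C * n
        z = np.zeros(n)
        it = 0
        converged = False
        for it in range(1, self.max_iter + 1):
            w_old = w.copy()
            p_hat = expit(z)
            gb = C * np.sum(p_hat - y01)
            b_new = b - gb / Lb
            z += b_new - b
            b = b_new
            for j in range(p):
                p_hat = expit(z)
                g = C * Xs[:, j] @ (p_hat - y01)
                u = w[j] - g / L[j]
                w_new = np.sign(u) * max(abs(u) - 1.0 / L[j], 0.0)
                if w_new != w[j]:
                    z += Xs[:, j] * (w_new - w[j])
                    w[j] = w_new
            if np.max(np.abs(w - w_old)) < self.tol:
                converged = True
                break
        return w, b, it, converged

    def _fit_l1(self, Xs, y01):
        """Internal CV over the penalty path with a one-SE rule.

        The path is anchored by the empty (majority-vote) model as its
        sparsest endpoint, so on uninformative data the rule can select no
        features at all rather than the weakest penalty that happened to win
        a noisy fold comparison.
        """
        cs = np.logspace(-2.5, 1.0, 13) if self.cs is None else np.asarray(self.cs)
        skf = RepeatedStratifiedKFold(
            n_splits=self.cv, n_repeats=3, random_state=self.random_state
        )
        folds = list(skf.split(Xs, y01))
        acc = np.zeros((len(cs) + 1, len(folds)))
        for k, (tr, te) in enumerate(folds):
            majority = 1.0 if y01[tr].mean() >= 0.5 else 0.0
            acc[0, k] = np.mean((y01[te] > 0.5) == (majority > 0.5))
        for ic, C in enumerate(cs):
            for k, (tr, te) in enumerate(folds):
                w, b, _, _ = self._l1_path_fit(Xs[tr], y01[tr], C)
                pred = (Xs[te] @ w + b) > 0
                acc[ic + 1, k] = np.mean(pred == (y01[te] > 0.5))
        mean = acc.mean(axis=1)
        # repeated folds are correlated; use the number of distinct splits,
        # not the number of repeats, as the effective sample size
        se = acc.std(axis=1, ddof=1) / np.sqrt(self.cv)
        best = int(np.argmax(mean))
        # one-SE rule: the sparsest candidate whose accuracy is within one
        # standard error of the best (candidates ordered sparsest first)
        ok = mean >= mean[best] - se[best]
        chosen = int(np.argmax(ok))
        if chosen == 0:  # empty model: intercept-only majority vote
            self.C_ = 0.0
            b = float(np.log(y01.mean() / (1.0 - y01.mean()))) if 0 < y01.mean() < 1 else 0.0
            return np.zeros(Xs.shape[1]), b, 1, True
        w, b, it, converged = self._l1_path_fit(Xs, y01, cs[chosen - 1])
        self.C_ = float(cs[chosen - 1])
        w = self._canonicalize_duplicates(Xs, w)
        return w, b, it, converged

    @staticmethod
    def _canonicalize_duplicates(Xs, w):
        """Concentrate weight on the first of numerically identical columns.

        With exactly collinear columns the L1 optimum is non-unique along
        their span (loss and penalty are both invariant to transfers between
        aligned duplicates); coordinate solvers land on arbitrary splits.
        Pick the representative with the weight on the first column.
        """
        nz = np.where(np.abs(w) > _WEIGHT_EPS)[0]
        for a_i, i in enumerate(nz):
            if abs(w[i]) <= _WEIGHT_EPS:
                continue
            for j in nz[a_i + 1:]:
                if abs(w[j]) <= _WEIGHT_EPS:
                    continue
                if np.allclose(Xs[:, i], Xs[:, j], atol=1e-10):
                    sign = 1.0
                elif np.allclose(Xs[:, i], -Xs[:, j], atol=1e-10):
                    sign = -1.0
                else:
                    continue
                if abs(w[i] + sign * w[j]) <= abs(w[i]) + abs(w[j]) + 1e-15:
                    w[i] += sign * w[j]
                    w[j] = 0.0
        return w

    # -- public API ---------------------------------------------------------

    def fit(self, X, y):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y01 = self._encode(y)
        Xs, self.feature_mean_, self.feature_scale_ = self._standardize(X)
        if self.variant in ("slr-lap", "slr-var"):
            w, b, alpha, active, it, conv = self._fit_ard(Xs, y01)
            self.relevance_ = alpha
            selected = active[np.abs(w[active]) > _WEIGHT_EPS]
        else:
            w, b, it, conv = self._fit_l1(Xs, y01)
            self.relevance_ = None
            selected = np.where(np.abs(w) > _WEIGHT_EPS)[0]
        self.coef_ = w
        self.intercept_ = b
        self.selected_ = selected
        self.n_iter_ = it
        self.converged_ = conv
        return self

    def decision_function(self, X):
        Xs = (np.asarray(X, dtype=float) - self.feature_mean_) / self.feature_scale_
        return Xs @ self.coef_ + self.intercept_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1 - p1, p1])


def fit_slr(
    fm,
    variant: str = "l1-slr-lap",
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
    **kwargs,
) -> SLRFit:
    """Fit one SLR variant on a :class:`~mirebound.features.FeatureMatrix`
    (or a plain ``(X, y)`` tuple) and return the sparse fit summary."""
    if isinstance(fm, tuple):
        X, y = fm
        names = None
    else:
        X, y, names = fm.values, fm.labels, list(fm.feature_names)
    est = SparseLogisticRegression(
        variant=variant, max_iter=max_iter, tol=tol, random_state=seed, **kwargs
    )
    est.fit(X, y)
    return SLRFit(
        variant=VARIANT_LABELS[variant],
        weights=est.coef_,
        intercept=float(est.intercept_),
        relevance=est.relevance_,
        selected=est.selected_,
        iterations=est.n_iter_,
        converged=est.converged_,
        feature_names=names,
    )
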