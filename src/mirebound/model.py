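"""SVM classification, cross-validation and selection-then-classification.

The classifier is a soft-margin kernel SVM behind a per-fold standardization
step; hyperparameters (kernel family, penalty, kernel scale) can be searched
by nested cross-validation.  Feature selection (any SLR variant) is fitted
inside each training fold so no test information leaks into the selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix
from .slr import VARIANT_LABELS, VARIANTS, SLRFit, fit_slr

__all__ = [
    "ClassificationReport",
    "fit_svm",
    "cross_validate",
    "select_then_classify",
    "compare_selectors",
    "save_model",
    "load_model",
]

_PERSISTENCE_FORMAT = 1

DEFAULT_SEARCH_SPACE = [
    {"svc__kernel": ["linear"], "svc__C": [0.1, 1.0, 10.0]},
    {
        "svc__kernel": ["rbf"],
        "svc__C": [0.1, 1.0, 10.0, 100.0],
        "svc__gamma": ["scale", 0.01, 0.1],
    },
    {
        "svc__kernel": ["poly"],
        "svc__C": [0.1, 1.0, 10.0],
        "svc__degree": [2, 3],
        "svc__gamma": ["scale"],
    },
]


@dataclass
class ClassificationReport:
    """k-fold cross-validation outcome."""

    fold_accuracies: np.ndarray  # percent, one per fold
    mean_accuracy: float  # percent, pooled over folds
    confusion: np.ndarray  # 2x2 counts averaged over folds
    per_class_recall: np.ndarray  # percent, one per class
    classes: np.ndarray
    folds: int
    seed: int
    features_left: float | None = None
    fold_selected: list[np.ndarray] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "fold_accuracies": [round(float(a), 6) for a in self.fold_accuracies],
            "mean_accuracy": round(float(self.mean_accuracy), 6),
            "confusion_matrix": self.confusion.tolist(),
            "per_class_recall": [round(float(r), 6) for r in self.per_class_recall],
            "classes": [str(c) for c in self.classes],
            "folds": int(self.folds),
            "seed": int(self.seed),
        }
        if self.features_left is not None:
            d["features_left"] = float(self.features_left)
        return d


def _unpack(fm) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(fm, FeatureMatrix):
        return fm.values, fm.labels
    X, y = fm
    return np.asarray(X, dtype=float), np.asarray(y)


def fit_svm(
    fm,
    optimize: bool = False,
    search_space=None,
    seed: int = 0,
):
    """Train a standardized soft-margin SVM, optionally with a CV search over
    kernel family and parameters.  Deterministic under a fixed seed."""
    X, y = _unpack(fm)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("fit_svm needs at least two classes")
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svc", SVC(kernel="rbf", C=1.0, gamma="scale"))]
    )
    if optimize:
        inner_k = int(min(5, counts.min()))
        if inner_k < 2:
            raise ValueError("too few trials per class for hyperparameter search")
        search = GridSearchCV(
            pipe,
            search_space or DEFAULT_SEARCH_SPACE,
            cv=StratifiedKFold(inner_k, shuffle=True, random_state=seed),
            scoring="accuracy",
            n_jobs=1,
        )
        search.fit(X, y)
        return search.best_estimator_
    pipe.fit(X, y)
    return pipe


def _aggregate(
    fold_acc, conf_sum, classes, k, seed, features_left=None, fold_selected=None
) -> ClassificationReport:
    total = conf_sum.sum()
    mean_acc = 100.0 * np.trace(conf_sum) / total
    with np.errstate(invalid="ignore"):
        recall = 100.0 * np.diag(conf_sum) / conf_sum.sum(axis=1)
    return ClassificationReport(
        fold_accuracies=np.asarray(fold_acc),
        mean_accuracy=float(mean_acc),
        confusion=conf_sum / k,
        per_class_recall=recall,
        classes=classes,
        folds=k,
        seed=seed,
        features_left=features_left,
        fold_selected=fold_selected or [],
    )


def cross_validate(
    fm,
    k: int = 10,
    seed: int = 0,
    optimize: bool = False,
    search_space=None,
) -> ClassificationReport:
    """Stratified k-fold CV of the SVM; standardization (and the optional
    hyperparameter search) is refit inside each training fold."""
    X, y = _unpack(fm)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"minority class has {counts.min()} trials < k={k}; use a smaller k"
        )
    skf = StratifiedKFold(k, shuffle=True, random_state=seed)
    fold_acc = []
    conf_sum = np.zeros((len(classes), len(classes)))
    for tr, te in skf.split(X, y):
        model = fit_svm((X[tr], y[tr]), optimize=optimize, search_space=search_space, seed=seed)
        pred = model.predict(X[te])
        fold_acc.append(100.0 * np.mean(pred == y[te]))
        conf_sum += _sk_confusion(y[te], pred, labels=classes)
    return _aggregate(fold_acc, conf_sum, classes, k, seed)


def select_then_classify(
    fm: FeatureMatrix,
    variant: str = "l1-slr-lap",
    k: int = 10,
    seed: int = 0,
    optimize: bool = False,
) -> tuple[SLRFit, ClassificationReport]:
    """SLR feature selection inside each training fold, then an SVM on the
    selected columns.

    The report carries the median number of surviving features across folds
    (``features_left``) and the per-fold selections.  The returned
    :class:`SLRFit` is refit on the full data for inspection of the weights.
    A fold whose selection comes back empty falls back to the full feature
    set with a warning.
    """
    X, y = fm.values, fm.labels
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"minority class has {counts.min()} trials < k={k}; use a smaller k"
        )
    skf = StratifiedKFold(k, shuffle=True, random_state=seed)
    fold_acc = []
    conf_sum = np.zeros((len(classes), len(classes)))
    fold_selected = []
    n_left = []
    for tr, te in skf.split(X, y):
        sel_fit = fit_slr((X[tr], y[tr]), variant=variant, seed=seed)
        sel = sel_fit.selected
        if len(sel) == 0:
            warnings.warn("selection emptied the feature set; using all features")
            sel = np.arange(X.shape[1])
        fold_selected.append(sel)
        n_left.append(len(sel))
        model = fit_svm((X[tr][:, sel], y[tr]), optimize=optimize, seed=seed)
        pred = model.predict(X[te][:, sel])
        fold_acc.append(100.0 * np.mean(pred == y[te]))
        conf_sum += _sk_confusion(y[te], pred, labels=classes)
    full_fit = fit_slr(fm, variant=variant, seed=seed)
    report = _aggregate(
        fold_acc,
        conf_sum,
        classes,
        k,
        seed,
        features_left=float(np.median(n_left)),
        fold_selected=fold_selected,
    )
    return full_fit, report


def save_model(model, path) -> None:
    """Persist a fitted model (pipeline or SLR fit) with a format version."""
    import joblib

    joblib.dump({"format_version": _PERSISTENCE_FORMAT, "model": model}, path)


def load_model(path):
    """Load a model saved by :func:`save_model`, checking the format."""
    import joblib

    payload = joblib.load(path)
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError("not a recognized model container")
    if payload["format_version"] > _PERSISTENCE_FORMAT:
        raise ValueError(
            f"container format {payload['format_version']} is newer than supported"
        )
    return payload["model"]


def compare_selectors(
    fm: FeatureMatrix,
    variants=VARIANTS,
    k: int = 10,
    seed: int = 0,
    optimize: bool = False,
) -> pd.DataFrame:
    """One row per model: plain SVM plus each SLR variant, with the number of
    surviving features and the CV accuracy (table layout: Models /
    Features Left / Accuracy)."""
    rows = []
    base = cross_validate(fm, k=k, seed=seed, optimize=optimize)
    rows.append(
        {"model": "SVM", "features_left": fm.n_features, "accuracy_pct": base.mean_accuracy}
    )
    for v in variants:
        _, rep = select_then_classify(fm, variant=v, k=k, seed=seed, optimize=optimize)
        rows.append(
            {
                "model": VARIANT_LABELS[v],
                "features_left": rep.features_left,
                "accuracy_pct": rep.mean_accuracy,
            }
        )
    return pd.DataFrame(rows)
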