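"""Connectome classification: t-test feature screen + linear SVM.

The protocol the coreness features feed into: within every training fold,
features are screened by a two-sample t-test (p < 0.05 uncorrected by
default), standardized on training statistics, and a linear support
vector machine is fit; nothing is ever estimated on test samples.
Cross-validation schemes: leave-one-out (deterministic, run once),
repeated stratified k-fold (reshuffled per repeat), and one-vs-rest for
multiclass problems. Reported metrics are accuracy, sensitivity (on the
designated positive class) and specificity.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core_io import ValidationError

FALLBACK_N_FEATURES = 50

__all__ = ["ClassificationResult", "ttest_feature_select", "loocv_classify",
           "repeated_kfold_classify", "one_vs_rest_multiclass"]


@dataclasses.dataclass
class ClassificationResult:
    """Cross-validated performance of the screened linear SVM."""

    accuracy: float
    sensitivity: float
    specificity: float
    predictions: np.ndarray           # per-sample CV prediction
    n_selected_per_fold: list[int]
    config: dict


def _two_sample_t_p(X: np.ndarray, y01: np.ndarray) -> np.ndarray:
    import scipy.stats
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = scipy.stats.ttest_ind(X[y01 == 0], X[y01 == 1], axis=0)
    return np.where(np.isfinite(p), p, 1.0)


def ttest_feature_select(X_train: np.ndarray, y_train: np.ndarray,
                         p_threshold: float = 0.05) -> np.ndarray:
    """Feature ids whose training-fold two-sample t-test has p < threshold.

    Uses training data only. If nothing passes the screen, falls back to
    the 50 smallest-p features with a warning (a classifier needs input).
    """
    X_train = np.asarray(X_train, dtype=float)
    classes = np.unique(y_train)
    if classes.size != 2:
        raise ValidationError(f"feature screen needs 2 training classes, got {classes.size}")
    y01 = (np.asarray(y_train) == classes[1]).astype(int)
    p = _two_sample_t_p(X_train, y01)
    selected = np.flatnonzero(p < p_threshold)
    if selected.size == 0:
        m = min(FALLBACK_N_FEATURES, p.size)
        warnings.warn(
            f"no feature passed p < {p_threshold}; falling back to the {m} smallest-p features",
            RuntimeWarning, stacklevel=2,
        )
        selected = np.argsort(p, kind="stable")[:m]
    return selected


def _fit_predict_fold(X, y, train_idx, test_idx, p_threshold, C):
    sel = ttest_feature_select(X[train_idx], y[train_idx], p_threshold)
    scaler = StandardScaler().fit(X[np.ix_(train_idx, sel)])
    clf = SVC(kernel="linear", C=C)
    clf.fit(scaler.transform(X[np.ix_(train_idx, sel)]), y[train_idx])
    Xt = scaler.transform(X[np.ix_(test_idx, sel)])
    return clf.predict(Xt), clf.decision_function(Xt), sel.size


def _metrics(y_true, y_pred, pos_label) -> tuple[float, float, float]:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    acc = float(np.mean(y_true == y_pred))
    pos = y_true == pos_label
    sens = float(np.mean(y_pred[pos] == pos_label)) if pos.any() else np.nan
    spec = float(np.mean(y_pred[~pos] != pos_label)) if (~pos).any() else np.nan
    return acc, sens, spec


def loocv_classify(X: np.ndarray, y: np.ndarray, p_threshold: float = 0.05,
                   C: float = 1.0, pos_label=None) -> ClassificationResult:
    """Leave-one-out CV of the screened linear SVM (deterministic).

    Sensitivity is reported on ``pos_label`` (default: the larger class
    label in sorted order, i.e. the task/deprived condition when labels
    are 0=rest/control, 1=task/deprived).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < 4:
        raise ValidationError(f"need >= 4 samples, got {X.shape[0]}")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError(f"binary protocol needs 2 classes, got {classes.size}")
    if pos_label is None:
        pos_label = classes[-1]
    preds = np.empty(X.shape[0], dtype=y.dtype)
    valid = np.ones(X.shape[0], dtype=bool)
    n_sel = []
    for train_idx, test_idx in LeaveOneOut().split(X):
        if np.unique(y[train_idx]).size < 2:
            warnings.warn("a training fold lost a class; skipping that fold",
                          RuntimeWarning, stacklevel=2)
            valid[test_idx] = False
            continue
        yp, _, ns = _fit_predict_fold(X, y, train_idx, test_idx, p_threshold, C)
        preds[test_idx] = yp
        n_sel.append(ns)
    acc, sens, spec = _metrics(y[valid], preds[valid], pos_label)
    return ClassificationResult(
        accuracy=acc, sensitivity=sens, specificity=spec, predictions=preds,
        n_selected_per_fold=n_sel,
        config={"cv": "loo", "p_threshold": p_threshold, "C": C,
                "pos_label": pos_label},
    )


def repeated_kfold_classify(X: np.ndarray, y: np.ndarray, k: int = 10,
                            repeats: int = 100, seed: int = 0,
                            p_threshold: float = 0.05, C: float = 1.0,
                            ) -> tuple[float, float]:
    """Mean and sd of accuracy over ``repeats`` reshuffled stratified k-folds."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k > X.shape[0]:
        raise ValidationError(f"k={k} exceeds n={X.shape[0]}")
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValidationError(
            f"k={k} folds infeasible with smallest class of {counts.min()} samples"
        )
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(repeats):
        cv = StratifiedKFold(n_splits=k, shuffle=True,
                             random_state=int(rng.integers(2**31 - 1)))
        correct = 0
        for train_idx, test_idx in cv.split(X, y):
            yp, _, _ = _fit_predict_fold(X, y, train_idx, test_idx, p_threshold, C)
            correct += int(np.sum(yp == y[test_idx]))
        accs.append(correct / X.shape[0])
    return float(np.mean(accs)), float(np.std(accs))


def one_vs_rest_multiclass(X: np.ndarray, y_multi: np.ndarray,
                           p_threshold: float = 0.05, C: float = 1.0,
                           ) -> tuple[dict, float]:
    """One-vs-rest LOOCV multiclass protocol.

    One screened binary SVM per class (class vs pooled rest), each with
    its own within-fold feature selection; the prediction is the class
    whose classifier has the largest decision value. Returns per-class
    one-vs-rest accuracies and the overall multiclass accuracy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_multi)
    classes = np.unique(y)
    if classes.size < 3:
        raise ValidationError(f"one-vs-rest needs >= 3 classes, got {classes.size}")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValidationError("every class needs >= 2 samples")
    n = X.shape[0]
    decision = np.empty((n, classes.size))
    ovr_correct = np.zeros(classes.size)
    for ci, cls in enumerate(classes):
        y_bin = (y == cls).astype(int)
        for train_idx, test_idx in LeaveOneOut().split(X):
            _, dec, _ = _fit_predict_fold(X, y_bin, train_idx, test_idx,
                                          p_threshold, C)
            decision[test_idx, ci] = dec
            ovr_correct[ci] += int(bool(dec[0] > 0) == bool(y_bin[test_idx][0]))
    preds = classes[np.argmax(decision, axis=1)]
    per_class = {str(cls): float(ovr_correct[ci] / n) for ci, cls in enumerate(classes)}
    return per_class, float(np.mean(preds == y))
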