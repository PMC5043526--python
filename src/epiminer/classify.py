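"""Two-class SVM region classification and backward feature selection.

Predictors are standardised inside each cross-validation fold (train-fold
mean/SD) to avoid leakage; radial and Laplacian kernel bandwidths default
to the median heuristic on the standardised training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.metrics import auc, roc_curve
from sklearn.metrics.pairwise import laplacian_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["ClassifierReport", "SVMModel", "RFEResult",
           "train_svm", "predict", "rfe_select"]

_KERNELS = ("linear", "radial", "laplacian")


def _median_gamma(X: np.ndarray, metric: str) -> float:
    """Median-heuristic kernel width: gamma = 1 / median pairwise distance²
    (radial) or distance (laplacian)."""
    n = len(X)
    if n > 500:  # subsample for the median; heuristic only needs the scale
        rng = np.random.default_rng(0)
        X = X[rng.choice(n, 500, replace=False)]
    d = pdist(X, metric="sqeuclidean" if metric == "radial" else "cityblock")
    med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return 1.0 / med


def _make_svc(kernel: str, X_scaled: np.ndarray, C: float) -> SVC:
    if kernel == "linear":
        return SVC(kernel="linear", C=C)
    if kernel == "radial":
        return SVC(kernel="rbf", C=C, gamma=_median_gamma(X_scaled, "radial"))
    if kernel == "laplacian":
        gamma = _median_gamma(X_scaled, "laplacian")
        return SVC(kernel=lambda a, b: laplacian_kernel(a, b, gamma=gamma), C=C)
    raise ValueError(f"kernel must be one of {_KERNELS}")


@dataclass
class ClassifierReport:
    kernel: str
    k: int
    fold_predictions: pd.DataFrame  # index=row id: decision value, label, fold
    roc: pd.DataFrame               # FPR, TPR points
    auc: float
    accuracy: float


@dataclass
class SVMModel:
    kernel: str
    predictors: list[str]
    scaler: StandardScaler
    svc: SVC

    def decision(self, X: pd.DataFrame) -> np.ndarray:
        missing = [p for p in self.predictors if p not in X.columns]
        if missing:
            raise ValueError(f"missing predictor column(s): {missing}")
        Xs = self.scaler.transform(X[self.predictors].to_numpy(dtype=float))
        return self.svc.decision_function(Xs)


def _check_labels(y: np.ndarray) -> tuple[str, str]:
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    return classes[0], classes[1]  # alphabetical; positive = the greater label


def train_svm(X: pd.DataFrame, y, kernel: str = "radial", k: int = 10,
              C: float = 1.0, seed: int | None = None,
              positive_label=None) -> tuple[SVMModel, ClassifierReport]:
    """Stratified k-fold cross-validated SVM with pooled out-of-fold ROC.

    Out-of-fold decision values from every fold are pooled into a single
    ROC curve; AUC is its trapezoid area. The returned model is refit on
    the full data.
    """
    y = np.asarray([str(v) for v in y])
    neg, pos = _check_labels(y)
    if positive_label is not None:
        pos = str(positive_label)
        neg = next(c for c in set(y) if c != pos)
    counts = pd.Series(y).value_counts()
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smaller class size {counts.min()}; use a smaller k")
    Xv = X.to_numpy(dtype=float)
    ybin = (y == pos).astype(int)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    decisions = np.zeros(len(y))
    folds = np.zeros(len(y), dtype=int)
    for fold, (tr, te) in enumerate(skf.split(Xv, ybin)):
        scaler = StandardScaler().fit(Xv[tr])
        Xtr, Xte = scaler.transform(Xv[tr]), scaler.transform(Xv[te])
        svc = _make_svc(kernel, Xtr, C)
        svc.fit(Xtr, ybin[tr])
        decisions[te] = svc.decision_function(Xte)
        folds[te] = fold

    fpr, tpr, _ = roc_curve(ybin, decisions)
    report = ClassifierReport(
        kernel=kernel, k=k,
        fold_predictions=pd.DataFrame(
            {"decision": decisions, "label": y, "fold": folds}, index=X.index),
        roc=pd.DataFrame({"FPR": fpr, "TPR": tpr}),
        auc=float(auc(fpr, tpr)),
        accuracy=float(((decisions > 0).astype(int) == ybin).mean()),
    )
    scaler = StandardScaler().fit(Xv)
    svc = _make_svc(kernel, scaler.transform(Xv), C)
    svc.fit(scaler.transform(Xv), ybin)
    model = SVMModel(kernel, [str(c) for c in X.columns], scaler, svc)
    model.positive = pos
    model.negative = neg
    return model, report


def predict(model: SVMModel, X: pd.DataFrame) -> pd.DataFrame:
    """Labels plus decision values for new quantified ROIs."""
    if len(X) == 0:
        return pd.DataFrame(columns=["label", "decision"])
    dec = model.decision(X)
    labels = np.where(dec > 0, getattr(model, "positive", "positive"),
                      getattr(model, "negative", "negative"))
    return pd.DataFrame({"label": labels, "decision": dec}, index=X.index)


def _cv_accuracy(Xv: np.ndarray, ybin: np.ndarray, k: int, C: float,
                 seed: int | None) -> float:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(Xv, ybin):
        scaler = StandardScaler().fit(Xv[tr])
        svc = SVC(kernel="linear", C=C)
        svc.fit(scaler.transform(Xv[tr]), ybin[tr])
        correct += (svc.predict(scaler.transform(Xv[te])) == ybin[te]).sum()
    return correct / len(ybin)


@dataclass
class RFEResult:
    accuracy_by_size: pd.Series      # subset size -> CV accuracy of best subset
    subsets: dict[int, list[str]]    # subset size -> predictors retained
    selected: list[str]              # best compact combination
    best_size: int


def rfe_select(X: pd.DataFrame, y, k: int = 10, C: float = 1.0,
               seed: int | None = None, tolerance: float = 0.01) -> RFEResult:
    """Backward feature elimination with per-step cross-validated accuracy.

    Starting from all predictors, each step drops the predictor whose
    removal least degrades k-fold CV accuracy (linear SVM), recording the
    accuracy-vs-size curve. The selected set is the smallest subset whose
    accuracy is within `tolerance` of the best accuracy on the curve.
    """
    if X.shape[1] < 2:
        raise ValueError("need >= 2 predictors")
    y = np.asarray([str(v) for v in y])
    _check_labels(y)
    ybin = (y == sorted(set(y))[1]).astype(int)
    current = [str(c) for c in X.columns]
    acc: dict[int, float] = {}
    subsets: dict[int, list[str]] = {}

    acc[len(current)] = _cv_accuracy(X[current].to_numpy(float), ybin, k, C, seed)
    subsets[len(current)] = list(current)
    while len(current) > 1:
        scores = []
        for drop in current:
            reduced = [c for c in current if c != drop]
            a = _cv_accuracy(X[reduced].to_numpy(float), ybin, k, C, seed)
            scores.append((a, drop))
        best_a, drop = max(scores, key=lambda t: t[0])
        current = [c for c in current if c != drop]
        acc[len(current)] = best_a
        subsets[len(current)] = list(current)

    series = pd.Series(acc).sort_index()
    best = series.max()
    best_size = int(min(s for s, a in series.items() if a >= best - tolerance))
    return RFEResult(series, subsets, subsets[best_size], best_size)
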