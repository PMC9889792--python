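"""SVM promoter classification, algorithm benchmarking, and the metric
suite under stratified k-fold cross-validation.

The classifier operates on 99-dimensional DDS feature vectors; the default
configuration is an RBF-kernel support-vector machine with C = 1.0 and the
variance-scaled kernel width (``gamma="scale"``).  No feature
standardization is applied by default; ``standardize=True`` z-scores
within each training fold to stay leakage-safe.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import cohen_kappa_score, confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dds import DimensionError, FeatureMatrix

KERNELS = ("rbf", "polynomial", "linear", "sigmoid")
ALGORITHMS = ("svm", "lda", "cart", "knn")

PERCENT_METRICS = ("accuracy", "precision", "recall", "specificity")


def _as_xy(X, y=None):
    if isinstance(X, FeatureMatrix):
        labels = X.position_labels
        X = X.values
    else:
        X = np.asarray(X, dtype=float)
        labels = None
    if y is not None:
        y = np.asarray(y, dtype=int)
        if len(y) != X.shape[0]:
            raise DimensionError("X and y lengths differ")
    return X, y, labels


@dataclass
class TrainedModel:
    """A fitted binary promoter classifier plus its provenance."""

    estimator: object
    kernel: str
    C: float
    gamma: str | float
    position_labels: np.ndarray | None
    n_training: int
    seed: int

    @property
    def n_features(self) -> int:
        return self.estimator.n_features_in_

    def _check_width(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise DimensionError(
                f"model expects width {self.n_features}, got {X.shape}"
            )
        return X

    def predict(self, X) -> np.ndarray:
        X, _, _ = _as_xy(X)
        return self.estimator.predict(self._check_width(X))

    def decision_scores(self, X) -> np.ndarray:
        """Signed decision-function values (0 is the class boundary)."""
        X, _, _ = _as_xy(X)
        X = self._check_width(X)
        est = self.estimator
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(X), dtype=float)
        proba = est.predict_proba(X)[:, 1]
        return np.asarray(proba - 0.5, dtype=float)

    def save(self, path: str | Path) -> None:
        """Persist to a binary with a JSON provenance sidecar."""
        path = Path(path)
        joblib.dump(self.estimator, path)
        sidecar = {
            "format_version": 1,
            "kernel": self.kernel,
            "C": self.C,
            "gamma": self.gamma,
            "position_labels": None
            if self.position_labels is None
            else [int(p) for p in self.position_labels],
            "n_training": self.n_training,
            "seed": self.seed,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        labels = meta["position_labels"]
        return cls(
            estimator=joblib.load(path),
            kernel=meta["kernel"],
            C=meta["C"],
            gamma=meta["gamma"],
            position_labels=None if labels is None else np.asarray(labels, dtype=int),
            n_training=meta["n_training"],
            seed=meta["seed"],
        )


def _make_estimator(
    algorithm: str,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: str | float = "scale",
    seed: int = 0,
    standardize: bool = False,
):
    if algorithm == "svm":
        if kernel not in KERNELS:
            raise ValueError(f"unknown kernel {kernel!r}; expected one of {KERNELS}")
        sk_kernel = "poly" if kernel == "polynomial" else kernel
        est = SVC(kernel=sk_kernel, C=C, gamma=gamma, random_state=seed)
    elif algorithm == "lda":
        est = LinearDiscriminantAnalysis()
    elif algorithm == "cart":
        est = DecisionTreeClassifier(random_state=seed)
    elif algorithm == "knn":
        est = KNeighborsClassifier()
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    if standardize:
        est = Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def train_classifier(
    X,
    y,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: str | float = "scale",
    seed: int = 0,
    standardize: bool = False,
    algorithm: str = "svm",
) -> TrainedModel:
    """Fit a promoter classifier on a DDS feature matrix."""
    X, y, labels = _as_xy(X, y)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    est = _make_estimator(algorithm, kernel, C, gamma, seed, standardize)
    est.fit(X, y)
    return TrainedModel(
        estimator=est,
        kernel=kernel if algorithm == "svm" else algorithm,
        C=C,
        gamma=gamma,
        position_labels=labels,
        n_training=X.shape[0],
        seed=seed,
    )


def confusion_metrics(y_true, y_pred) -> dict[str, float]:
    """Accuracy/precision/recall/specificity (%) and Cohen's kappa.

    A ratio with a zero denominator is reported as NaN (undefined), never
    silently as 0.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise DimensionError("y_true and y_pred lengths differ")
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    n = tn + fp + fn + tp

    def ratio(num, den):
        return float(num) / float(den) if den else float("nan")

    return {
        "accuracy": 100.0 * ratio(tp + tn, n),
        "precision": 100.0 * ratio(tp, tp + fp),
        "recall": 100.0 * ratio(tp, tp + fn),
        "specificity": 100.0 * ratio(tn, tn + fp),
        "kappa": float(cohen_kappa_score(y_true, y_pred)),
    }


def roc_auc(y_true, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR over all score thresholds) and trapezoid AUC."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC needs both classes present")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain non-finite values")
    fpr, tpr, _ = roc_curve(y_true, scores)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


@dataclass(frozen=True)
class FoldReport:
    """Per-fold metrics and their mean ± sd under stratified k-fold CV."""

    per_fold: pd.DataFrame
    fold_hash: str
    seed: int
    algorithm: str
    kernel: str

    @property
    def k(self) -> int:
        return len(self.per_fold)

    @property
    def mean(self) -> pd.Series:
        return self.per_fold.mean()

    @property
    def sd(self) -> pd.Series:
        return self.per_fold.std(ddof=1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


def _fold_indices(X: np.ndarray, y: np.ndarray, k: int, seed: int):
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(X, y))


def _hash_folds(folds) -> str:
    h = hashlib.sha256()
    for _, test_idx in folds:
        h.update(np.asarray(test_idx, dtype=np.int64).tobytes())
        h.update(b"|")
    return h.hexdigest()[:16]


def stratified_cv(
    X,
    y,
    k: int = 10,
    algorithm: str = "svm",
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: str | float = "scale",
    seed: int = 0,
    standardize: bool = False,
) -> FoldReport:
    """Stratified k-fold cross-validation (default tenfold, 0.9/0.1
    train/test per fold) reporting the full metric suite per fold."""
    X, y, _ = _as_xy(X, y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need two classes for cross-validation")
    if counts.min() < k:
        raise ValueError(f"k={k} exceeds the smallest class size {counts.min()}")
    folds = _fold_indices(X, y, k, seed)
    rows = []
    for train_idx, test_idx in folds:
        est = _make_estimator(algorithm, kernel, C, gamma, seed, standardize)
        est.fit(X[train_idx], y[train_idx])
        y_pred = est.predict(X[test_idx])
        row = confusion_metrics(y[test_idx], y_pred)
        if hasattr(est, "decision_function"):
            scores = est.decision_function(X[test_idx])
        else:
            scores = est.predict_proba(X[test_idx])[:, 1]
        try:
            _, _, row["auc"] = roc_auc(y[test_idx], scores)
        except ValueError:
            row["auc"] = float("nan")
        rows.append(row)
    return FoldReport(
        per_fold=pd.DataFrame(rows),
        fold_hash=_hash_folds(folds),
        seed=seed,
        algorithm=algorithm,
        kernel=kernel if algorithm == "svm" else "",
    )


def benchmark_algorithms(
    X,
    y,
    algorithms: Sequence[str] = ALGORITHMS,
    k: int = 10,
    seed: int = 0,
    kernel: str = "rbf",
) -> pd.DataFrame:
    """Mean CV metrics per algorithm, all algorithms on identical folds."""
    results = []
    for alg in algorithms:
        if alg not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {alg!r}; expected one of {ALGORITHMS}")
        report = stratified_cv(X, y, k=k, algorithm=alg, kernel=kernel, seed=seed)
        row = report.mean.to_dict()
        row.update({"algorithm": alg, "fold_hash": report.fold_hash})
        results.append(row)
    cols = ["algorithm", *PERCENT_METRICS, "kappa", "auc", "fold_hash"]
    return pd.DataFrame(results)[cols]
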