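"""Window classification: random-forest core model plus comparators.

The screening classifier labels each 60-s window as apneic or normal
from its combined multiscale-entropy + PRV feature vector.  The core
model is a random forest; SVM, k-NN and gradient-boosted comparators
are available through the same interface for benchmarking.  Evaluation
uses the usual confusion-matrix identities

    Se = TP / (TP + FN),  Sp = TN / (TN + FP),
    Acc = (TP + TN) / (TP + FP + TN + FN).
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd

from .mse import SampEnParams
from .prv import impute_columns, select_features

MODEL_KINDS = ("rf", "svm", "knn", "xgb")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    runtime_s: float = 0.0


def _make_estimator(model_kind: str, seed: int, n_estimators: int = 500):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    if model_kind == "rf":
        return RandomForestClassifier(n_estimators=n_estimators,
                                      random_state=seed, n_jobs=1)
    if model_kind == "svm":
        return make_pipeline(StandardScaler(),
                             SVC(kernel="rbf", random_state=seed))
    if model_kind == "knn":
        return make_pipeline(StandardScaler(),
                             KNeighborsClassifier(n_neighbors=5))
    if model_kind == "xgb":
        from xgboost import XGBClassifier
        return XGBClassifier(n_estimators=200, max_depth=4,
                             learning_rate=0.1, random_state=seed,
                             n_jobs=1, verbosity=0)
    raise ValueError(f"unknown model kind {model_kind!r}; "
                     f"choose from {MODEL_KINDS}")


def train_model(features, labels, model_kind: str = "rf", seed: int = 0,
                n_estimators: int = 500):
    """Fit one window classifier; deterministic under a fixed seed."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("feature matrix must be 2-D and non-empty")
    if np.unique(y).size < 2:
        raise ValueError("training needs at least two classes")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain NaN/inf; impute first")
    est = _make_estimator(model_kind, seed, n_estimators)
    est.fit(X, y)
    return est


def evaluate(predictions, truth) -> tuple[ConfusionCounts, Metrics]:
    """Confusion counts and Se/Sp/Acc; undefined ratios come back NaN."""
    pred = np.asarray(predictions).astype(bool)
    true = np.asarray(truth).astype(bool)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth lengths differ")
    counts = ConfusionCounts(
        tp=int(np.sum(pred & true)),
        tn=int(np.sum(~pred & ~true)),
        fp=int(np.sum(pred & ~true)),
        fn=int(np.sum(~pred & true)),
    )

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    metrics = Metrics(
        accuracy=ratio(counts.tp + counts.tn, counts.total),
        sensitivity=ratio(counts.tp, counts.tp + counts.fn),
        specificity=ratio(counts.tn, counts.tn + counts.fp),
    )
    return counts, metrics


def benchmark_models(features, labels, seed: int = 0, test_size: float = 0.3,
                     kinds=MODEL_KINDS) -> pd.DataFrame:
    """Per-model Acc/Se/Sp and wall time on a stratified hold-out split."""
    from sklearn.model_selection import train_test_split

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.size == 0:
        raise ValueError("empty feature matrix")
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_size, random_state=seed, stratify=y)
    rows = []
    for kind in kinds:
        t0 = time.perf_counter()
        est = train_model(Xtr, ytr, model_kind=kind, seed=seed)
        pred = est.predict(Xte)
        dt = time.perf_counter() - t0
        _, m = evaluate(pred, yte)
        rows.append({"model": kind, "accuracy": m.accuracy,
                     "sensitivity": m.sensitivity,
                     "specificity": m.specificity, "runtime_s": dt})
    return pd.DataFrame(rows)


@dataclass
class ApneaWindowModel:
    """A trained window classifier bundled with its preprocessing state.

    Carries the fitted estimator, the training-time imputation medians,
    the embedded feature-selection mask, the column names and the entropy
    parameters, so that prediction on a raw (possibly NaN-bearing)
    feature matrix is reproducible.
    """

    estimator: object
    columns: list[str]
    impute_medians: np.ndarray
    selection_mask: np.ndarray
    sampen_params: SampEnParams = field(default_factory=SampEnParams)
    coarse_method: str = "improved"
    model_kind: str = "rf"
    seed: int = 0

    @classmethod
    def fit(cls, raw_features: np.ndarray, labels, columns: list[str],
            model_kind: str = "rf", seed: int = 0, select: bool = True,
            importance_threshold: float | None = None,
            sampen_params: SampEnParams | None = None,
            coarse_method: str = "improved") -> "ApneaWindowModel":
        raw = np.asarray(raw_features, dtype=float)
        X, _, medians = impute_columns(raw)
        if select:
            mask = select_features(X, labels,
                                   importance_threshold=importance_threshold,
                                   seed=seed)
            if not mask.any():
                mask = np.ones(X.shape[1], dtype=bool)
        else:
            mask = np.ones(X.shape[1], dtype=bool)
        est = train_model(X[:, mask], labels, model_kind=model_kind,
                          seed=seed)
        return cls(est, list(columns), medians, mask,
                   sampen_params or SampEnParams(), coarse_method,
                   model_kind, seed)

    def predict(self, raw_features: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw_features, dtype=float)
        X, _, _ = impute_columns(raw, self.impute_medians)
        return self.estimator.predict(X[:, self.selection_mask]).astype(bool)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ApneaWindowModel":
        return joblib.load(path)
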