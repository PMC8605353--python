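"""Classifiers over contextual feature vectors and the metric suite.

Two model families are supported: gradient-boosted trees (XGBoost,
logistic objective, eta 0.2, max_depth 4) and a dense two-hidden-layer
feed-forward network (ReLU hidden layers, logistic output, Adam,
L2 weight decay). All performance metrics are computed directly from
the confusion matrix; AUC is trapezoidal over the score sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

METRIC_NAMES = ["accuracy", "sensitivity", "specificity", "precision",
                "f1", "mcc", "auc"]


@dataclass
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            TP=int(((y_true == 1) & (y_pred == 1)).sum()),
            TN=int(((y_true == 0) & (y_pred == 0)).sum()),
            FP=int(((y_true == 0) & (y_pred == 1)).sum()),
            FN=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def confusion_matrix_metrics(cm: ConfusionMatrix) -> dict:
    """Acc, Sn, Sp, Precision, F1 and MCC from the four counts.

    Undefined ratios (empty denominators) are reported as NaN, except
    MCC which is 0 when its denominator vanishes.
    """
    TP, TN, FP, FN = cm.TP, cm.TN, cm.FP, cm.FN

    def ratio(num, den):
        return num / den if den else float("nan")

    acc = ratio(TP + TN, cm.total)
    sn = ratio(TP, TP + FN)
    sp = ratio(TN, TN + FP)
    prec = ratio(TP, TP + FP)
    f1 = (2 * prec * sn / (prec + sn)
          if not (math.isnan(prec) or math.isnan(sn)) and (prec + sn) > 0
          else (0.0 if not (math.isnan(prec) or math.isnan(sn)) else float("nan")))
    denom = math.sqrt((TP + FP) * (TP + FN) * (TN + FP) * (TN + FN))
    mcc = (TP * TN - FP * FN) / denom if denom > 0 else 0.0
    return {"accuracy": acc, "sensitivity": sn, "specificity": sp,
            "precision": prec, "f1": f1, "mcc": mcc}


def auc_trapezoidal(y_true, scores) -> float:
    """Area under the ROC curve by trapezoidal integration over the
    threshold sweep across all observed scores."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # threshold boundaries at distinct scores only
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.concatenate((distinct, [len(y_sorted) - 1]))
    tpr = np.concatenate(([0.0], tps[idx] / n_pos))
    fpr = np.concatenate(([0.0], fps[idx] / n_neg))
    return float(np.trapezoid(tpr, fpr))


@dataclass
class ModelSpec:
    """Hyperparameter container for the two model families.

    gbt defaults follow the grid-search optimum (learning rate 0.2,
    max depth 4, 1000 rounds, logistic objective, logloss eval). dnn
    defaults are the desk-scale configuration: two hidden layers of
    1024 ReLU units, Adam at 0.005, L2 1e-4, batch 128, up to 100
    epochs with early stopping.
    """

    kind: str = "gbt"
    learning_rate: float = 0.2
    max_depth: int = 4
    n_estimators: int = 1000
    hidden_units: tuple = (1024, 1024)
    dnn_learning_rate: float = 0.005
    l2: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 100
    early_stopping_patience: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gbt", "dnn"):
            raise ValueError("kind must be 'gbt' or 'dnn'")


class BindingSiteClassifier:
    """Binary classifier separating bound from unbound motif contexts.

    sklearn-style estimator; ``kind='gbt'`` wraps XGBoost, ``kind='dnn'``
    wraps a two-hidden-layer MLP. Deterministic under ``random_state``
    (single-threaded for gbt by default).
    """

    def __init__(self, kind: str = "gbt", learning_rate: float = 0.2,
                 max_depth: int = 4, n_estimators: int = 1000,
                 hidden_units: tuple = (1024, 1024),
                 dnn_learning_rate: float = 0.005, l2: float = 1e-4,
                 batch_size: int = 128, max_epochs: int = 100,
                 early_stopping_patience: int = 10,
                 threshold: float = 0.5, n_jobs: int = 1,
                 random_state: int = 0):
        self.kind = kind
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.n_estimators = n_estimators
        self.hidden_units = hidden_units
        self.dnn_learning_rate = dnn_learning_rate
        self.l2 = l2
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stopping_patience = early_stopping_patience
        self.threshold = threshold
        self.n_jobs = n_jobs
        self.random_state = random_state

    _param_names = ("kind", "learning_rate", "max_depth", "n_estimators",
                    "hidden_units", "dnn_learning_rate", "l2", "batch_size",
                    "max_epochs", "early_stopping_patience", "threshold",
                    "n_jobs", "random_state")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "BindingSiteClassifier":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @classmethod
    def from_spec(cls, spec: ModelSpec, **overrides) -> "BindingSiteClassifier":
        return cls(kind=spec.kind, learning_rate=spec.learning_rate,
                   max_depth=spec.max_depth, n_estimators=spec.n_estimators,
                   hidden_units=spec.hidden_units,
                   dnn_learning_rate=spec.dnn_learning_rate, l2=spec.l2,
                   batch_size=spec.batch_size, max_epochs=spec.max_epochs,
                   early_stopping_patience=spec.early_stopping_patience,
                   random_state=spec.rng_seed, **overrides)

    def fit(self, X, y) -> "BindingSiteClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if np.isnan(X).any():
            raise ValueError("feature matrix contains NaN")
        if self.kind == "gbt":
            from xgboost import XGBClassifier

            self._model = XGBClassifier(
                learning_rate=self.learning_rate, max_depth=self.max_depth,
                n_estimators=self.n_estimators, objective="binary:logistic",
                eval_metric="logloss", base_score=float(np.mean(y)),
                tree_method="hist", n_jobs=self.n_jobs,
                random_state=self.random_state, verbosity=0)
            self._model.fit(X, y)
        else:
            from sklearn.neural_network import MLPClassifier

            batch = min(self.batch_size, len(y))
            self._model = MLPClassifier(
                hidden_layer_sizes=tuple(self.hidden_units),
                activation="relu", solver="adam",
                learning_rate_init=self.dnn_learning_rate, alpha=self.l2,
                batch_size=batch, max_iter=self.max_epochs,
                early_stopping=True,
                n_iter_no_change=self.early_stopping_patience,
                random_state=self.random_state)
            self._model.fit(X, y)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "_model"):
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature-count mismatch with the fitted schema")
        return self._model.predict_proba(X)

    def decision_scores(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= self.threshold).astype(int)

    def score(self, X, y) -> float:
        return float((self.predict(X) == np.asarray(y).astype(int)).mean())


def evaluate(model: BindingSiteClassifier, X, y, threshold: float = 0.5
             ) -> tuple[ConfusionMatrix, dict]:
    """Confusion matrix and the full metric suite on held-out data."""
    scores = model.decision_scores(X)
    pred = (scores >= threshold).astype(int)
    cm = ConfusionMatrix.from_predictions(y, pred)
    metrics = confusion_matrix_metrics(cm)
    metrics["auc"] = auc_trapezoidal(y, scores)
    return cm, metrics


def _stratified_split(y: np.ndarray, train_fraction: float, rng
                      ) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        order = rng.permutation(len(idx))
        n_train = int(round(train_fraction * len(idx)))
        train_idx.append(idx[order[:n_train]])
        test_idx.append(idx[order[n_train:]])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def repeated_cv(X, y, model: BindingSiteClassifier, rounds: int = 10,
                train_fraction: float = 0.7, master_seed: int = 0
                ) -> pd.DataFrame:
    """Repeated random 70:30 holdout: each round reshuffles with a
    derived seed, retrains from scratch and evaluates on the held-out
    fraction. Returns per-round metrics plus mean/sd rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    rows = []
    for r in range(rounds):
        seed = (master_seed * 100003 + r) % (2**31 - 1)
        rng = np.random.default_rng(seed)
        tr, te = _stratified_split(y, train_fraction, rng)
        m = BindingSiteClassifier(**{**model.get_params(), "random_state": seed})
        m.fit(X[tr], y[tr])
        _, metrics = evaluate(m, X[te], y[te])
        metrics["round"] = r
        rows.append(metrics)
    df = pd.DataFrame(rows).set_index("round")
    summary = pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)}).T
    return pd.concat([df, summary])


def select_dinucleotide_window(train_sequences: Sequence[str], train_labels,
                               candidate_sizes: Sequence[int],
                               model: Optional[BindingSiteClassifier] = None,
                               val_fraction: float = 0.3,
                               master_seed: int = 0) -> int:
    """Pick the dinucleotide window size whose features alone best
    separate the classes on an internal validation split.

    Ties resolve to the smaller window; a single candidate is returned
    unchanged.
    """
    from .features import ContextFeaturizer

    sizes = sorted(candidate_sizes)
    if not sizes:
        raise ValueError("no candidate sizes")
    if len(sizes) == 1:
        return sizes[0]
    y = np.asarray(train_labels).astype(int)
    rng = np.random.default_rng(master_seed)
    tr, va = _stratified_split(y, 1.0 - val_fraction, rng)
    seqs = list(train_sequences)
    if model is None:
        model = BindingSiteClassifier(kind="gbt", n_estimators=100,
                                      random_state=master_seed)
    best_size, best_acc = sizes[0], -1.0
    for size in sizes:
        fz = ContextFeaturizer(window_size=size, use_pentamer=False,
                               use_heptamer=False)
        fz.fit([seqs[i] for i in tr], y[tr])
        Xtr = fz.transform([seqs[i] for i in tr])
        Xva = fz.transform([seqs[i] for i in va])
        m = BindingSiteClassifier(**model.get_params())
        m.fit(Xtr, y[tr])
        acc = m.score(Xva, y[va])
        if acc > best_acc:  # strict: ties keep the smaller (earlier) size
            best_size, best_acc = size, acc
    return best_size
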