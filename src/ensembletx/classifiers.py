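"""The 12 classifier adapters behind a single fit/score contract.

Every adapter consumes a plain numeric feature matrix and binary labels
(case=1, control=0) and produces one finite real score per sample, higher
meaning more case-like. Probabilistic classifiers score with the positive
class probability; margin classifiers with the signed decision value;
regression-type models ("reg", "ridgeReg", "lassoReg") with the raw
prediction — ranking metrics downstream only need a monotone score, so no
thresholding is applied.

Hyperparameter grids are small fixed defaults; when a grid has more than one
point the adapter picks the best by AUC-ROC on an inner stratified 75/25
split of its training data, then refits on all of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import (BaggingClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import Lasso, LinearRegression, LogisticRegression, Ridge
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .metrics import auc_roc

CLASSIFIER_IDS = [
    "reg", "logReg", "lda", "qda", "ridgeReg", "lassoReg", "ridgeLogReg",
    "lassoLogReg", "elasticNetLogReg", "boosting", "randomForest", "bagging",
]


class FitInfeasible(Exception):
    """Typed signal: this classifier cannot be fit on this data.

    Recorded by the harness, never propagated as a crash.
    """


def _grid(**kwargs):
    """Expand a dict of lists into a list of dicts (cartesian)."""
    keys = list(kwargs)
    combos = [{}]
    for k in keys:
        combos = [{**c, k: v} for c in combos for v in kwargs[k]]
    return combos


_GRIDS: dict[str, list[dict]] = {
    "reg": [{}],
    "logReg": [{}],
    "lda": [{}],
    "qda": [{}],
    "ridgeReg": _grid(alpha=[0.1, 1.0, 10.0]),
    "lassoReg": _grid(alpha=[0.01, 0.1]),
    "ridgeLogReg": _grid(C=[0.1, 1.0, 10.0]),
    "lassoLogReg": _grid(C=[0.1, 1.0]),
    "elasticNetLogReg": [{"C": 1.0, "l1_ratio": 0.5}],
    "boosting": [{"n_estimators": 50, "max_depth": 2}],
    "randomForest": [{"n_estimators": 32}],
    "bagging": [{"n_estimators": 16}],
}

_NEEDS_SCALING = {"reg", "logReg", "lda", "qda", "ridgeReg", "lassoReg",
                  "ridgeLogReg", "lassoLogReg", "elasticNetLogReg"}


def _build(classifier_id: str, params: dict, seed: int):
    if classifier_id == "reg":
        return LinearRegression()
    if classifier_id == "logReg":
        return LogisticRegression(penalty=None, max_iter=500)
    if classifier_id == "lda":
        return LinearDiscriminantAnalysis()
    if classifier_id == "qda":
        return QuadraticDiscriminantAnalysis()
    if classifier_id == "ridgeReg":
        return Ridge(**params)
    if classifier_id == "lassoReg":
        return Lasso(max_iter=5000, **params)
    if classifier_id == "ridgeLogReg":
        return LogisticRegression(penalty="l2", max_iter=500, **params)
    if classifier_id == "lassoLogReg":
        return LogisticRegression(penalty="l1", solver="liblinear", **params)
    if classifier_id == "elasticNetLogReg":
        return LogisticRegression(penalty="elasticnet", solver="saga",
                                  max_iter=300, tol=1e-3, **params)
    if classifier_id == "boosting":
        # gradient boosting with the binomial (Bernoulli) deviance loss
        return GradientBoostingClassifier(random_state=seed, **params)
    if classifier_id == "randomForest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if classifier_id == "bagging":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(max_depth=4, random_state=seed),
            random_state=seed, **params)
    raise KeyError(f"unknown classifier id: {classifier_id}")


@dataclass
class ClassifierAdapter:
    classifier_id: str
    hyperparameters: dict = field(default_factory=dict)
    _model: Any = None
    _scaler: Any = None

    def score(self, features: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("adapter not fitted")
        x = np.asarray(features, dtype=float)
        if self._scaler is not None:
            x = self._scaler.transform(x)
        m = self._model
        if hasattr(m, "predict_proba"):
            pos = int(np.where(m.classes_ == 1)[0][0])
            s = m.predict_proba(x)[:, pos]
        elif hasattr(m, "decision_function"):
            s = m.decision_function(x)
        else:
            s = m.predict(x)
        s = np.asarray(s, dtype=float)
        if not np.isfinite(s).all():
            raise FitInfeasible(f"{self.classifier_id} produced non-finite scores")
        return s


def fit_classifier(classifier_id: str, train_features, train_labels,
                   seed: int = 0) -> ClassifierAdapter:
    """Fit one of the 12 adapters; raises :class:`FitInfeasible` on degenerate input."""
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels, dtype=int)
    if x.ndim != 2 or len(y) != x.shape[0]:
        raise ValueError("train_features must be (n_samples, n_features) matching labels")
    if not np.isfinite(x).all():
        raise FitInfeasible("non-finite feature values")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise FitInfeasible("need at least 2 samples per class")
    if x.shape[1] == 0 or np.all(x.std(axis=0) == 0):
        raise FitInfeasible("no informative features (zero variance everywhere)")
    if classifier_id == "qda" and counts.min() <= x.shape[1]:
        # class covariance would be singular
        raise FitInfeasible("qda needs more samples per class than features")

    grid = _GRIDS[classifier_id]
    params = grid[0]
    if len(grid) > 1 and counts.min() >= 4:
        params = _select_params(classifier_id, grid, x, y, seed)

    adapter = ClassifierAdapter(classifier_id, dict(params))
    if classifier_id in _NEEDS_SCALING:
        adapter._scaler = StandardScaler().fit(x)
        x_fit = adapter._scaler.transform(x)
    else:
        x_fit = x
    model = _build(classifier_id, params, seed)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x_fit, y)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise FitInfeasible(f"{classifier_id}: {exc}") from exc
    adapter._model = model
    # fail fast on degenerate fits rather than at scoring time
    adapter.score(np.asarray(train_features, dtype=float)[:1])
    return adapter


def _select_params(classifier_id, grid, x, y, seed):
    """Pick grid point by AUC-ROC on an inner stratified 75/25 split."""
    idx_tr, idx_val = train_test_split(
        np.arange(len(y)), test_size=0.25, stratify=y, random_state=seed)
    best, best_auc = grid[0], -np.inf
    for params in grid:
        try:
            model = _build(classifier_id, params, seed)
            x_tr = x[idx_tr]
            scaler = None
            if classifier_id in _NEEDS_SCALING:
                scaler = StandardScaler().fit(x_tr)
                x_tr = scaler.transform(x_tr)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(x_tr, y[idx_tr])
            x_val = x[idx_val] if scaler is None else scaler.transform(x[idx_val])
            if hasattr(model, "predict_proba"):
                pos = int(np.where(model.classes_ == 1)[0][0])
                s = model.predict_proba(x_val)[:, pos]
            elif hasattr(model, "decision_function"):
                s = model.decision_function(x_val)
            else:
                s = model.predict(x_val)
            a = auc_roc(s, y[idx_val])
        except Exception:
            continue
        if a > best_auc:
            best, best_auc = params, a
    return best
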