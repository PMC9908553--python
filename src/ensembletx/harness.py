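"""Cross-validated training sweep, dual AUC gating, and permutation null.

The sweep evaluates every (route, classifier) spec by repeated stratified
holdout: in each of 5 iterations a seeded 20% of training samples is held
out, the route is fitted and the classifier trained on the remaining 80%,
and AUC-ROC / AUC-PR are computed on the held-out part. Routes are fitted
once per iteration and shared across the 12 classifiers. Specs whose route
or classifier fails in any iteration are marked infeasible and carry no AUC
values — mirroring selection methods that cannot find qualified features on
some folds.

Gating is two-staged: specs whose mean training-CV AUC-ROC reaches the
threshold (default 0.80) are refit on the full training set and scored once
on the held-out test set; those whose test AUC-ROC also reaches the
threshold survive. The label-permutation null re-runs the sweep on shuffled
diagnosis labels with an 85/15 split and pools all surviving mean AUC-ROC
values into a null distribution.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .classifiers import FitInfeasible, fit_classifier
from .metrics import auc_pr, auc_roc
from .routes import FeatureRoute, MethodRegistry, ModelSpec, RouteInfeasible, default_registry

logger = logging.getLogger(__name__)


@dataclass
class SweepConfig:
    n_iterations: int = 5
    holdout_frac: float = 0.2
    seed: int = 0
    classic_kfold: bool = False  # classic stratified 5-fold instead of repeated holdout


@dataclass
class ModelResult:
    spec: ModelSpec
    per_fold_auc_roc: list = field(default_factory=list)
    per_fold_auc_pr: list = field(default_factory=list)
    feasible: bool = True
    test_auc_roc: float | None = None
    test_auc_pr: float | None = None

    @property
    def mean_auc_roc(self) -> float:
        return float(np.mean(self.per_fold_auc_roc)) if self.feasible else np.nan

    @property
    def mean_auc_pr(self) -> float:
        return float(np.mean(self.per_fold_auc_pr)) if self.feasible else np.nan


@dataclass
class GateReport:
    n_feasible: int
    n_pass_train: int
    n_pass_both: int
    threshold: float


@dataclass
class FittedModel:
    """A gated spec refit on the full training set."""

    spec: ModelSpec
    route: FeatureRoute
    adapter: object
    train_cv_auc_roc: float
    train_scores: np.ndarray  # scores on the full training set (commensuration bounds)
    test_auc_roc: float | None = None
    test_auc_pr: float | None = None

    def predict(self, matrix: np.ndarray) -> np.ndarray:
        return self.adapter.score(self.route.transform(matrix))


def _splits(y: np.ndarray, config: SweepConfig):
    if config.classic_kfold:
        kf = StratifiedKFold(n_splits=config.n_iterations, shuffle=True,
                             random_state=config.seed % 2**31)
        return list(kf.split(np.zeros(len(y)), y))
    sss = StratifiedShuffleSplit(n_splits=config.n_iterations,
                                 test_size=config.holdout_frac,
                                 random_state=config.seed % 2**31)
    return list(sss.split(np.zeros(len(y)), y))


def run_training_sweep(specs: list[ModelSpec], train_matrix: np.ndarray,
                       train_labels: np.ndarray, config: SweepConfig | None = None,
                       registry: MethodRegistry | None = None,
                       feature_names=None) -> list[ModelResult]:
    """Evaluate every spec by seeded stratified holdout iterations.

    ``train_matrix`` is samples x genes (log scale, preprocessed).
    """
    if not specs:
        raise ValueError("specs must be nonempty")
    config = config or SweepConfig()
    registry = registry or default_registry()
    x = np.asarray(train_matrix, dtype=float)
    y = np.asarray(train_labels, dtype=int)

    results = {spec: ModelResult(spec) for spec in specs}
    route_ids = sorted({spec.route_id for spec in specs})
    specs_by_route: dict = {rid: [s for s in specs if s.route_id == rid]
                            for rid in route_ids}

    for it, (idx_tr, idx_val) in enumerate(_splits(y, config)):
        fit_seed = (config.seed + 7919 * (it + 1)) % 2**31
        x_tr, y_tr = x[idx_tr], y[idx_tr]
        x_val, y_val = x[idx_val], y[idx_val]
        for rid in route_ids:
            t0 = time.perf_counter()
            route = FeatureRoute(*rid, _registry=registry)
            try:
                route.fit(x_tr, y_tr, feature_names=feature_names, seed=fit_seed)
                f_tr = route.transform(x_tr)
                f_val = route.transform(x_val)
            except RouteInfeasible as exc:
                logger.debug("iter %d route %s infeasible: %s", it, rid, exc)
                for spec in specs_by_route[rid]:
                    results[spec].feasible = False
                continue
            for spec in specs_by_route[rid]:
                res = results[spec]
                if not res.feasible:
                    continue
                try:
                    adapter = fit_classifier(spec.classifier_id, f_tr, y_tr, seed=fit_seed)
                    scores = adapter.score(f_val)
                    res.per_fold_auc_roc.append(auc_roc(scores, y_val))
                    res.per_fold_auc_pr.append(auc_pr(scores, y_val))
                except FitInfeasible as exc:
                    logger.debug("iter %d spec %s infeasible: %s", it, spec, exc)
                    res.feasible = False
            logger.debug("iter %d route %s done in %.2fs", it, rid,
                         time.perf_counter() - t0)

    for res in results.values():
        if not res.feasible:
            res.per_fold_auc_roc = []
            res.per_fold_auc_pr = []
    return [results[s] for s in specs]


def gate_models(results: list[ModelResult], train_matrix, train_labels,
                test_matrix, test_labels, threshold: float = 0.80,
                registry: MethodRegistry | None = None, seed: int = 0,
                train_ids=None, test_ids=None,
                feature_names=None) -> tuple[list[FittedModel], GateReport]:
    """Dual gate: train-CV AUC-ROC >= threshold, then test AUC-ROC >= threshold.

    Train-passing specs are refit on the full training set before the single
    test scoring. When sample ids are supplied, train/test overlap is a hard
    error.
    """
    if train_ids is not None and test_ids is not None:
        overlap = set(train_ids) & set(test_ids)
        if overlap:
            raise ValueError(f"train/test sample overlap: {sorted(overlap)[:5]}")
    registry = registry or default_registry()
    x_tr = np.asarray(train_matrix, dtype=float)
    y_tr = np.asarray(train_labels, dtype=int)
    x_te = np.asarray(test_matrix, dtype=float)
    y_te = np.asarray(test_labels, dtype=int)

    feasible = [r for r in results if r.feasible]
    passing = [r for r in feasible if r.mean_auc_roc >= threshold]

    gated: list[FittedModel] = []
    route_cache: dict = {}
    for res in passing:
        rid = res.spec.route_id
        if rid not in route_cache:
            route = FeatureRoute(*rid, _registry=registry)
            try:
                route.fit(x_tr, y_tr, feature_names=feature_names, seed=seed)
                route_cache[rid] = route
            except RouteInfeasible:
                route_cache[rid] = None
        route = route_cache[rid]
        if route is None:
            continue
        try:
            f_tr = route.transform(x_tr)
            adapter = fit_classifier(res.spec.classifier_id, f_tr, y_tr, seed=seed)
            test_scores = adapter.score(route.transform(x_te))
        except FitInfeasible:
            continue
        t_roc = auc_roc(test_scores, y_te)
        res.test_auc_roc = t_roc
        res.test_auc_pr = auc_pr(test_scores, y_te)
        if t_roc >= threshold:
            gated.append(FittedModel(
                spec=res.spec, route=route, adapter=adapter,
                train_cv_auc_roc=res.mean_auc_roc,
                train_scores=adapter.score(f_tr),
                test_auc_roc=t_roc, test_auc_pr=res.test_auc_pr))

    report = GateReport(n_feasible=len(feasible), n_pass_train=len(passing),
                        n_pass_both=len(gated), threshold=threshold)
    return gated, report


def permutation_null(train_matrix, train_labels, specs: list[ModelSpec],
                     n_reps: int = 5, holdout_frac: float = 0.15,
                     n_iterations: int = 5, seed: int = 0,
                     registry: MethodRegistry | None = None,
                     feature_names=None) -> dict:
    """Label-permutation null distribution of model AUCs.

    Per replicate: diagnosis labels are shuffled, the sweep re-run with an
    85/15 train/validation split, and every feasible model's mean AUC-ROC and
    AUC-PR pooled. Returns the pooled arrays plus median and the 2.5/97.5
    percentiles of the AUC-ROC null.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(train_labels, dtype=int)
    pooled_roc, pooled_pr = [], []
    for rep in range(n_reps):
        y_perm = rng.permutation(y)
        config = SweepConfig(n_iterations=n_iterations, holdout_frac=holdout_frac,
                             seed=int(rng.integers(2**31)))
        results = run_training_sweep(specs, train_matrix, y_perm, config,
                                     registry=registry, feature_names=feature_names)
        pooled_roc.extend(r.mean_auc_roc for r in results if r.feasible)
        pooled_pr.extend(r.mean_auc_pr for r in results if r.feasible)
        logger.info("permutation replicate %d/%d: %d feasible models",
                    rep + 1, n_reps, sum(r.feasible for r in results))
    roc = np.asarray(pooled_roc)
    pr = np.asarray(pooled_pr)
    return {
        "auc_roc": roc,
        "auc_pr": pr,
        "median_auc_roc": float(np.median(roc)) if len(roc) else np.nan,
        "ci_low": float(np.percentile(roc, 2.5)) if len(roc) else np.nan,
        "ci_high": float(np.percentile(roc, 97.5)) if len(roc) else np.nan,
        "n_models_pooled": len(roc),
        "n_both_above_0.8": int(np.sum((roc > 0.8) & (pr > 0.8))) if len(roc) else 0,
    }
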