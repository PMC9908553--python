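"""Feature-engineering routes: filtration, selection, and reduction registries.

A *route* is an ordered triple (filtration, selection, reduction) that turns
a gene x sample expression matrix into the numeric features a classifier
consumes. The default registry carries 5 filtration methods, 102 selection
methods (seven families instantiated over documented parameter grids), and
7 reduction methods; crossed with the 12 classifiers this yields the
42,840-model grid the platform sweeps.

Routes obey a strict fit/transform contract: ``FeatureRoute.fit`` sees only
training-fold samples and stores all fitted state (selected feature ids,
reduction transform parameters); ``transform`` applies that state unchanged
to held-out samples. Routes that cannot produce at least one feature raise
:class:`RouteInfeasible`, which the harness records rather than propagates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.cross_decomposition import PLSRegression
from sklearn.feature_selection import f_classif, mutual_info_classif
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .classifiers import CLASSIFIER_IDS


class RouteInfeasible(Exception):
    """A route could not find qualified features on this training fold."""


class RegistryError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    filtration_id: str
    selection_id: str
    reduction_id: str
    classifier_id: str

    @property
    def route_id(self) -> tuple[str, str, str]:
        return (self.filtration_id, self.selection_id, self.reduction_id)


# ---------------------------------------------------------------------------
# filtration: unsupervised feature culling by dispersion, fitted on training data

FILTRATION_IDS = ["no", "cov", "var", "cov_var", "varImportance"]


def _keep_top(scores: np.ndarray, frac: float) -> np.ndarray:
    """Indices of the ceil(frac * n) features with the largest score."""
    n_keep = int(np.ceil(frac * len(scores)))
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:n_keep])


def filtration_mask(matrix: np.ndarray, method_id: str) -> np.ndarray:
    """Column indices retained by a filtration method.

    ``matrix`` is samples x features. cov drops the half with the smaller
    coefficient of variation; var the half with smaller variance; cov_var
    applies cov then var (retaining a quarter); varImportance keeps the
    quarter with highest variance.
    """
    n = matrix.shape[1]
    if method_id == "no":
        return np.arange(n)
    sd = matrix.std(axis=0, ddof=1)
    if method_id == "var":
        return _keep_top(sd, 0.5)
    if method_id == "varImportance":
        return _keep_top(sd, 0.25)
    mean = matrix.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.where(mean != 0, np.abs(sd / mean), np.inf)
    if method_id == "cov":
        return _keep_top(cov, 0.5)
    if method_id == "cov_var":
        first = _keep_top(cov, 0.5)
        second = _keep_top(sd[first], 0.5)
        return first[second]
    raise RegistryError(f"unknown filtration method: {method_id}")


def apply_filtration(matrix: np.ndarray, method_id: str) -> np.ndarray:
    if matrix.shape[1] < 4:
        raise ValueError("filtration requires at least 4 features")
    return matrix[:, filtration_mask(matrix, method_id)]


# ---------------------------------------------------------------------------
# selection families

_K_GRID = [10, 25, 50, 100, 250, 500]


def _group_stats(x: np.ndarray, y: np.ndarray):
    x1, x0 = x[y == 1], x[y == 0]
    return (x1.mean(axis=0), x0.mean(axis=0),
            x1.std(axis=0, ddof=1), x0.std(axis=0, ddof=1),
            len(x1), len(x0))


def _zscore_scores(x, y, stat):
    m1, m0, s1, s0, n1, n0 = _group_stats(x, y)
    eps = 1e-12
    if stat == "welch_t":
        return np.abs(m1 - m0) / np.sqrt(s1**2 / n1 + s0**2 / n0 + eps)
    if stat == "snr":
        return np.abs(m1 - m0) / (s1 + s0 + eps)
    if stat == "median_diff":
        x1, x0 = x[y == 1], x[y == 0]
        med1, med0 = np.median(x1, axis=0), np.median(x0, axis=0)
        mad1 = np.median(np.abs(x1 - med1), axis=0)
        mad0 = np.median(np.abs(x0 - med0), axis=0)
        return np.abs(med1 - med0) / (mad1 + mad0 + eps)
    raise RegistryError(f"unknown z-score statistic: {stat}")


def _ordinary_t_p(x, y):
    from scipy.stats import t as t_dist
    m1, m0, s1, s0, n1, n0 = _group_stats(x, y)
    df = n1 + n0 - 2
    sp2 = ((n1 - 1) * s1**2 + (n0 - 1) * s0**2) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n0)) + 1e-300
    t = (m1 - m0) / se
    return 2 * t_dist.sf(np.abs(t), df)


def _moderated_t_p(x, y):
    from .stats import moderated_t_arrays
    res = moderated_t_arrays(x[y == 1].T, x[y == 0].T)
    return res["p_value"]


def _ranksum_scores(x, y):
    # vectorized Mann-Whitney: distance of the rank-sum AUC from 0.5
    ranks = np.apply_along_axis(rankdata, 0, x)
    n1 = int((y == 1).sum())
    n0 = len(y) - n1
    u = ranks[y == 1].sum(axis=0) - n1 * (n1 + 1) / 2
    return np.abs(u / (n1 * n0) - 0.5)


def _svm_rfe(x, y, k, c):
    """Recursive feature elimination with a linear maximum-margin classifier."""
    idx = np.arange(x.shape[1])
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    xs = (x - x.mean(axis=0)) / sd
    while len(idx) > k:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            svc = LinearSVC(C=c, dual=False, max_iter=2000).fit(xs[:, idx], y)
        w = np.abs(svc.coef_.ravel())
        n_next = max(k, len(idx) // 2)
        keep = np.argsort(-w, kind="stable")[:n_next]
        idx = np.sort(idx[keep])
    return idx


def gene_set_collection(feature_names, set_size: int) -> list[np.ndarray]:
    """Deterministic synthetic gene-set collection: consecutive blocks of a
    name-hashed ordering, ``set_size`` genes each."""
    names = list(feature_names)
    order = np.random.default_rng(190000 + set_size).permutation(len(names))
    return [order[i:i + set_size] for i in range(0, len(names), set_size)
            if len(order[i:i + set_size]) >= 2]


def _gsea_enrichment(x, y, feature_names, set_size, m):
    """Running-sum enrichment of predefined sets against the group ranking."""
    corr_like = _zscore_scores(x, y, "snr") * np.sign(
        x[y == 1].mean(axis=0) - x[y == 0].mean(axis=0))
    order = np.argsort(-corr_like, kind="stable")
    rank_of = np.empty(len(order), dtype=int)
    rank_of[order] = np.arange(len(order))
    weights = np.abs(corr_like)
    sets = gene_set_collection(feature_names, set_size)
    n = x.shape[1]
    scores = []
    for members in sets:
        member_mask = np.zeros(n, dtype=bool)
        member_mask[members] = True
        in_set = member_mask[order]
        w = weights[order] * in_set
        denom = w.sum()
        if denom == 0:
            scores.append(0.0)
            continue
        hit = np.cumsum(w) / denom
        miss = np.cumsum(~in_set) / max(n - in_set.sum(), 1)
        run = hit - miss
        scores.append(run[np.argmax(np.abs(run))])
    top = np.argsort(-np.abs(np.asarray(scores)), kind="stable")[:m]
    keep = np.unique(np.concatenate([sets[i] for i in top])) if len(top) else np.array([], int)
    return keep


def _grn_degree(x, k, score):
    """Top-k hub genes of a co-expression relevance network.

    Edges are the top 1% of off-diagonal association strengths (absolute
    correlation, or binned mutual information); genes rank by degree.
    """
    if score == "pearson":
        assoc = np.abs(np.corrcoef(x.T))
    elif score == "spearman":
        ranks = np.apply_along_axis(rankdata, 0, x)
        assoc = np.abs(np.corrcoef(ranks.T))
    elif score == "mi":
        assoc = _binned_mi(x)
    else:
        raise RegistryError(f"unknown grn score: {score}")
    np.fill_diagonal(assoc, 0.0)
    assoc = np.nan_to_num(assoc)
    thresh = np.quantile(assoc[np.triu_indices_from(assoc, k=1)], 0.99)
    degree = (assoc >= thresh).sum(axis=1)
    return np.sort(np.argsort(-degree, kind="stable")[:k])


def _binned_mi(x, n_bins: int = 3, chunk: int = 512) -> np.ndarray:
    """Pairwise mutual information after per-gene quantile discretization."""
    n, p = x.shape
    ranks = np.apply_along_axis(rankdata, 0, x)
    bins = np.minimum((ranks - 1) * n_bins // n, n_bins - 1).astype(int)
    ind = np.zeros((p, n_bins, n), dtype=np.float32)
    for b in range(n_bins):
        ind[:, b, :] = (bins.T == b)
    flat = ind.reshape(p * n_bins, n)
    marg = flat.sum(axis=1).reshape(p, n_bins) / n
    mi = np.zeros((p, p), dtype=np.float32)
    for start in range(0, p, chunk):
        stop = min(start + chunk, p)
        joint = (flat[start * n_bins: stop * n_bins] @ flat.T) / n
        joint = joint.reshape(stop - start, n_bins, p, n_bins)
        # outer product of marginals, shaped (chunk, bins, p, bins)
        outer = np.einsum("ib,jc->ibjc", marg[start:stop], marg)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = joint * np.log(joint / outer)
        mi[start:stop] = np.nansum(term, axis=(1, 3))
    return mi.astype(float)


@dataclass(frozen=True)
class SelectionMethod:
    method_id: str
    family: str
    params: dict = field(default_factory=dict)


def default_selection_methods() -> list[SelectionMethod]:
    """The 102-method selection registry (seven families over parameter grids)."""
    methods: list[SelectionMethod] = [SelectionMethod("no", "no")]
    for stat in ("welch_t", "snr", "median_diff"):
        for k in _K_GRID:
            methods.append(SelectionMethod(f"zscore:{stat}:k{k}", "zscore",
                                           {"stat": stat, "k": k}))
    for k in _K_GRID:
        methods.append(SelectionMethod(f"de:moderated:k{k}", "de",
                                       {"variant": "moderated", "k": k}))
    for k in _K_GRID[1:]:
        methods.append(SelectionMethod(f"de:ordinary:k{k}", "de",
                                       {"variant": "ordinary", "k": k}))
    for stat in ("f_stat", "mutual_info", "rank_sum"):
        for k in _K_GRID:
            methods.append(SelectionMethod(f"select:{stat}:k{k}", "select",
                                           {"stat": stat, "k": k}))
    for c in (0.01, 1.0, 100.0):
        for k in _K_GRID:
            methods.append(SelectionMethod(f"svm:C{c:g}:k{k}", "svm",
                                           {"C": c, "k": k}))
    for set_size, label in ((20, "small"), (50, "medium"), (100, "large")):
        for m in (5, 10, 20, 30, 50, 75):
            methods.append(SelectionMethod(f"gsea:{label}:m{m}", "gsea",
                                           {"set_size": set_size, "m": m}))
    for score in ("pearson", "spearman", "mi"):
        for k in _K_GRID:
            methods.append(SelectionMethod(f"grn:{score}:k{k}", "grn",
                                           {"score": score, "k": k}))
    return methods


def apply_selection(train_matrix: np.ndarray, labels: np.ndarray,
                    method: SelectionMethod, feature_names=None,
                    seed: int = 0) -> np.ndarray:
    """Feature indices chosen on the training fold by one selection method."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("selection requires both classes present")
    x = np.asarray(train_matrix, dtype=float)
    n_features = x.shape[1]
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(n_features)]

    fam, p = method.family, method.params
    k = min(p.get("k", n_features), n_features)
    if fam == "no":
        return np.arange(n_features)
    if fam == "zscore":
        return np.sort(np.argsort(-_zscore_scores(x, y, p["stat"]), kind="stable")[:k])
    if fam == "de":
        pv = _moderated_t_p(x, y) if p["variant"] == "moderated" else _ordinary_t_p(x, y)
        return np.sort(np.argsort(pv, kind="stable")[:k])
    if fam == "select":
        if p["stat"] == "f_stat":
            with np.errstate(divide="ignore", invalid="ignore"):
                scores = np.nan_to_num(f_classif(x, y)[0])
        elif p["stat"] == "mutual_info":
            scores = mutual_info_classif(x, y, random_state=seed)
        else:
            scores = _ranksum_scores(x, y)
        return np.sort(np.argsort(-scores, kind="stable")[:k])
    if fam == "svm":
        return _svm_rfe(x, y, k, p["C"])
    if fam == "gsea":
        keep = _gsea_enrichment(x, y, feature_names, p["set_size"], p["m"])
        if len(keep) == 0:
            raise RouteInfeasible("gsea selected no genes")
        return keep
    if fam == "grn":
        return _grn_degree(x, k, p["score"])
    raise RegistryError(f"unknown selection family: {fam}")


# ---------------------------------------------------------------------------
# reduction

REDUCTION_IDS = ["no", "wgcna", "logisticFwd", "sis", "pcr", "plsr", "cppls"]


class _IdentityReduction:
    def fit(self, x, y):
        return self

    def transform(self, x):
        return x


class _SubsetReduction:
    """Reductions that pick a feature subset (sis, logisticFwd)."""

    def __init__(self, picker: Callable):
        self._picker = picker
        self.indices_: np.ndarray | None = None

    def fit(self, x, y):
        self.indices_ = self._picker(x, y)
        if len(self.indices_) == 0:
            raise RouteInfeasible("reduction kept no features")
        return self

    def transform(self, x):
        return x[:, self.indices_]


def _sis_pick(x, y):
    """Sure-independence screening: top d = floor(n / log n) by |marginal corr|."""
    n = len(y)
    d = max(1, int(n / np.log(n)))
    d = min(d, x.shape[1])
    yc = y - y.mean()
    xc = x - x.mean(axis=0)
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum()) + 1e-300
    corr = np.abs(xc.T @ yc) / denom
    return np.sort(np.argsort(-corr, kind="stable")[:d])


def _logistic_forward_pick(x, y, max_features: int = 10):
    """Forward stepwise logistic selection with BIC stopping."""
    n = len(y)
    selected: list[int] = []
    remaining = list(range(x.shape[1]))
    # BIC of the intercept-only model
    p1 = y.mean()
    ll0 = n * (p1 * np.log(p1 + 1e-300) + (1 - p1) * np.log(1 - p1 + 1e-300))
    best_bic = -2 * ll0 + np.log(n)
    while remaining and len(selected) < max_features:
        # greedy: score candidates by marginal correlation first, try the top few
        resid_order = np.argsort(-np.abs(np.corrcoef(
            np.column_stack([x[:, remaining], y]).T)[-1, :-1]))
        candidates = [remaining[i] for i in resid_order[:25]]
        best_j, best_j_bic = None, best_bic
        for j in candidates:
            cols = selected + [j]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = LogisticRegression(penalty=None, max_iter=200).fit(x[:, cols], y)
                prob = np.clip(model.predict_proba(x[:, cols])[:, 1], 1e-12, 1 - 1e-12)
            ll = float(np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))
            bic = -2 * ll + np.log(n) * (len(cols) + 1)
            if bic < best_j_bic - 1e-9:
                best_j, best_j_bic = j, bic
        if best_j is None:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        best_bic = best_j_bic
    if not selected:
        raise RouteInfeasible("forward logistic selection kept no features")
    return np.array(sorted(selected))


class _EigengeneReduction:
    """Correlation-clustering eigengene extraction (WGCNA-style).

    Features are clustered by average-linkage on 1 - |corr| distance; the
    tree is cut at ``cut_height``; each module emits its first principal
    component, sign-anchored to a positive mean loading.
    """

    def __init__(self, cut_height: float = 0.75, random_state: int = 0):
        self.cut_height = cut_height
        self.random_state = random_state

    def fit(self, x, y):
        p = x.shape[1]
        self.mean_ = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        self.sd_ = sd
        xs = (x - self.mean_) / self.sd_
        if p == 1:
            self.modules_ = [np.array([0])]
        else:
            corr = np.corrcoef(xs.T)
            dist = np.clip(1.0 - np.abs(np.nan_to_num(corr)), 0.0, 2.0)
            np.fill_diagonal(dist, 0.0)
            # enforce symmetry before condensing
            dist = (dist + dist.T) / 2
            tree = average(squareform(dist, checks=False))
            labels = fcluster(tree, t=self.cut_height, criterion="distance")
            self.modules_ = [np.where(labels == m)[0] for m in np.unique(labels)]
        self.loadings_ = []
        for members in self.modules_:
            sub = xs[:, members]
            if len(members) == 1:
                v = np.array([1.0])
            else:
                # first right singular vector = first PC loadings
                _, _, vt = np.linalg.svd(sub, full_matrices=False)
                v = vt[0]
            if v.mean() < 0:
                v = -v
            self.loadings_.append(v / np.linalg.norm(v))
        return self

    def transform(self, x):
        xs = (x - self.mean_) / self.sd_
        cols = [xs[:, m] @ v for m, v in zip(self.modules_, self.loadings_)]
        return np.column_stack(cols)


class _PCRReduction:
    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, x, y):
        c = min(self.n_components, x.shape[1], x.shape[0] - 1)
        if c < 1:
            raise RouteInfeasible("not enough samples/features for PCA")
        self._pca = PCA(n_components=c).fit(x)
        return self

    def transform(self, x):
        return self._pca.transform(x)


class _PLSReduction:
    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, x, y):
        c = min(self.n_components, x.shape[1], x.shape[0] - 1)
        if c < 1:
            raise RouteInfeasible("not enough samples/features for PLS")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._pls = PLSRegression(n_components=c, scale=True).fit(x, y.astype(float))
        return self

    def transform(self, x):
        return self._pls.transform(x)


class _PoweredPLSReduction:
    """Canonical powered PLS: loading weights |corr|^gamma * sd^(1-gamma).

    The power ``gamma`` trades correlation against variance when forming each
    component's weight vector; gamma = 0.5 balances the two, gamma -> 1
    approaches correlation-only weights.
    """

    def __init__(self, n_components: int = 5, gamma: float = 0.5):
        self.n_components = n_components
        self.gamma = gamma

    def fit(self, x, y):
        c = min(self.n_components, x.shape[1], x.shape[0] - 1)
        if c < 1:
            raise RouteInfeasible("not enough samples/features for powered PLS")
        self.mean_ = x.mean(axis=0)
        xd = x - self.mean_
        yc = y.astype(float) - y.mean()
        self.weights_, self.loadings_ = [], []
        for _ in range(c):
            sd = xd.std(axis=0, ddof=1)
            denom = sd * yc.std(ddof=1) * (len(y) - 1) + 1e-300
            corr = (xd.T @ yc) / denom
            w = np.sign(corr) * (np.abs(corr) ** self.gamma) * (sd ** (1 - self.gamma))
            norm = np.linalg.norm(w)
            if norm < 1e-12:
                break
            w = w / norm
            t = xd @ w
            tt = float(t @ t)
            if tt < 1e-12:
                break
            p_load = xd.T @ t / tt
            xd = xd - np.outer(t, p_load)
            self.weights_.append(w)
            self.loadings_.append(p_load)
        if not self.weights_:
            raise RouteInfeasible("powered PLS extracted no components")
        return self

    def transform(self, x):
        xd = x - self.mean_
        scores = []
        for w, p_load in zip(self.weights_, self.loadings_):
            t = xd @ w
            scores.append(t)
            xd = xd - np.outer(t, p_load)
        return np.column_stack(scores)


def make_reduction(method_id: str, n_components: int = 5, seed: int = 0):
    if method_id == "no":
        return _IdentityReduction()
    if method_id == "wgcna":
        return _EigengeneReduction(random_state=seed)
    if method_id == "sis":
        return _SubsetReduction(_sis_pick)
    if method_id == "logisticFwd":
        return _SubsetReduction(_logistic_forward_pick)
    if method_id == "pcr":
        return _PCRReduction(n_components)
    if method_id == "plsr":
        return _PLSReduction(n_components)
    if method_id == "cppls":
        return _PoweredPLSReduction(n_components)
    raise RegistryError(f"unknown reduction method: {method_id}")


# ---------------------------------------------------------------------------
# registry and route

@dataclass
class MethodRegistry:
    filtration: list[str] = field(default_factory=lambda: list(FILTRATION_IDS))
    selection: list[SelectionMethod] = field(default_factory=default_selection_methods)
    reduction: list[str] = field(default_factory=lambda: list(REDUCTION_IDS))
    classifiers: list[str] = field(default_factory=lambda: list(CLASSIFIER_IDS))

    def selection_by_id(self, method_id: str) -> SelectionMethod:
        for m in self.selection:
            if m.method_id == method_id:
                return m
        raise RegistryError(f"unknown selection method: {method_id}")

    def subset(self, filtration=None, selection=None, reduction=None,
               classifiers=None) -> "MethodRegistry":
        return MethodRegistry(
            filtration=list(filtration) if filtration else list(self.filtration),
            selection=([self.selection_by_id(s) for s in selection]
                       if selection else list(self.selection)),
            reduction=list(reduction) if reduction else list(self.reduction),
            classifiers=list(classifiers) if classifiers else list(self.classifiers),
        )


def default_registry() -> MethodRegistry:
    return MethodRegistry()


#: Selections spanning all seven families but favoring the cheap members.
REDUCED_SELECTIONS = [
    "no", "zscore:welch_t:k50", "zscore:snr:k100", "de:moderated:k50",
    "de:ordinary:k100", "select:f_stat:k50", "select:rank_sum:k100",
    "svm:C1:k50", "gsea:medium:m10", "grn:pearson:k50",
]


def reduced_registry() -> MethodRegistry:
    """A 100-route (x 12 classifier) subset for desk-scale sweeps.

    2 filtrations x 10 selections x 5 reductions; every selection family is
    represented, with the cheaper grid points chosen so a full sweep stays
    interactive on one CPU.
    """
    return default_registry().subset(
        filtration=["no", "var"],
        selection=REDUCED_SELECTIONS,
        reduction=["no", "sis", "pcr", "plsr", "cppls"],
    )


def enumerate_specs(registry: MethodRegistry) -> list[ModelSpec]:
    """Deterministic ordered cross-product of the registry axes."""
    for axis in ("filtration", "selection", "reduction", "classifiers"):
        if not getattr(registry, axis):
            raise RegistryError(f"registry category {axis!r} is empty")
    return [ModelSpec(f, s.method_id, r, c)
            for f in registry.filtration
            for s in registry.selection
            for r in registry.reduction
            for c in registry.classifiers]


def enumerate_routes(registry: MethodRegistry) -> list[tuple[str, str, str]]:
    """The feature-route triples only (no classifier axis)."""
    return [(f, s.method_id, r)
            for f in registry.filtration
            for s in registry.selection
            for r in registry.reduction]


@dataclass
class FeatureRoute:
    """A fitted (filtration, selection, reduction) pipeline."""

    filtration_id: str
    selection_id: str
    reduction_id: str
    _registry: MethodRegistry = field(default_factory=default_registry, repr=False)
    _filter_idx: np.ndarray | None = None
    _select_idx: np.ndarray | None = None
    _reduction: Any = None

    def fit(self, train_matrix: np.ndarray, train_labels: np.ndarray,
            feature_names=None, seed: int = 0) -> "FeatureRoute":
        x = np.asarray(train_matrix, dtype=float)
        y = np.asarray(train_labels, dtype=int)
        if feature_names is None:
            feature_names = np.array([f"f{i}" for i in range(x.shape[1])])
        feature_names = np.asarray(feature_names)

        self._filter_idx = filtration_mask(x, self.filtration_id)
        xf = x[:, self._filter_idx]
        method = self._registry.selection_by_id(self.selection_id)
        sel = apply_selection(xf, y, method,
                              feature_names=feature_names[self._filter_idx],
                              seed=seed)
        if len(sel) == 0:
            raise RouteInfeasible("selection kept no features")
        self._select_idx = np.asarray(sel)
        xs = xf[:, self._select_idx]
        if np.allclose(xs.std(axis=0), 0):
            raise RouteInfeasible("selected features are constant")
        self._reduction = make_reduction(self.reduction_id, seed=seed)
        self._reduction.fit(xs, y)
        out = self._reduction.transform(xs)
        if out.shape[1] == 0:
            raise RouteInfeasible("reduction produced no features")
        return self

    @property
    def selected_features_(self) -> np.ndarray:
        return self._filter_idx[self._select_idx]

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if self._reduction is None:
            raise RuntimeError("route not fitted")
        x = np.asarray(matrix, dtype=float)
        return self._reduction.transform(x[:, self._filter_idx][:, self._select_idx])
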