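"""Downstream cohort statistics.

Implements the defined statistics the pipeline reports after classification:
empirical-Bayes moderated-t differential expression with Benjamini-Hochberg
adjustment and a log-fold-change gate, the two-sided Fisher exact test with a
conditional-MLE odds ratio (the estimate exact-test software reports), the
risk-gene mutation presence/absence classifier metrics, Welch's t, one-way
ANOVA, the Games-Howell unequal-variance post-hoc test, fixed age binning,
and the score ~ group * age regression.

The moderated t follows the standard empirical-Bayes treatment: gene-wise
residual variances s_g^2 (d_g df) are shrunk toward a prior (d0, s0^2)
estimated by closed-form moment matching of log s_g^2, giving posterior
variances

    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)

and t = logFC / (s~_g * sqrt(1/n1 + 1/n2)) on d0 + d_g df. d0 = 0 recovers
the ordinary t; d0 = infinity replaces every variance by s0^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .data import ConfusionCounts, ContingencyTable2x2

# --------------------------------------------------------------------------
# moderated t differential expression


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Closed-form moment matching of the marginal of s_g^2 on the log scale.

    Returns (d0, s0_squared); d0 may be ``inf`` when the observed variances
    are less dispersed than sampling alone would make them.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive gene variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    n = len(e)
    e_var = ((e - e_mean) ** 2).sum() / (n - 1)
    excess = e_var - special.polygamma(1, df / 2)
    if excess <= 0:
        # variances no more dispersed than sampling alone: complete pooling
        d0 = np.inf
        s0_sq = float(s2[ok].mean())
    else:
        d0 = 2 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_sq


def moderated_t_arrays(group1: np.ndarray, group2: np.ndarray,
                       prior: tuple[float, float] | None = None) -> dict:
    """Vectorized moderated t on genes x samples arrays (log scale).

    ``prior`` overrides the estimated (d0, s0^2); ``(0, anything)`` yields the
    ordinary two-sample t.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    logfc = g1.mean(axis=1) - g2.mean(axis=1)
    df_resid = n1 + n2 - 2
    rss = ((g1 - g1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((g2 - g2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = rss / df_resid

    if prior is None:
        d0, s0_sq = estimate_variance_prior(s2, df_resid)
    else:
        d0, s0_sq = prior

    # total df is capped at the pooled residual df across genes, so the
    # reference distribution stays a t even under complete pooling
    df_pooled = df_resid * len(s2)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = df_pooled
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = min(d0 + df_resid, df_pooled)

    se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / se
    # zero residual variance in both groups: infinite t guarded, p = 0
    infinite = ~np.isfinite(t)
    t = np.where(infinite, np.sign(logfc) * np.inf, t)
    p = 2 * sps.t.sf(np.abs(t), df_total)
    p = np.where(infinite, 0.0, p)
    return {"logfc": logfc, "t": t, "p_value": p, "s2": s2, "s2_post": s2_post,
            "d0": d0, "s0_sq": s0_sq, "df_total": df_total}


def moderated_t_de(expr_group1: pd.DataFrame, expr_group2: pd.DataFrame,
                   prior: tuple[float, float] | None = None,
                   adj_p_threshold: float = 0.01,
                   logfc_threshold: float = 0.1) -> pd.DataFrame:
    """Per-gene moderated-t differential expression table.

    Inputs are genes x samples log-expression frames sharing a gene index.
    Genes flagged significant satisfy adjusted p < 0.01 and |logFC| > 0.1.
    The returned table is volcano-plot ready (logFC, -log10 adjusted p).
    """
    if not expr_group1.index.equals(expr_group2.index):
        raise ValueError("gene indexes of the two groups differ")
    res = moderated_t_arrays(expr_group1.to_numpy(), expr_group2.to_numpy(), prior)
    adj = benjamini_hochberg(res["p_value"])
    with np.errstate(divide="ignore"):
        neglog = -np.log10(adj)
    return pd.DataFrame({
        "gene_id": expr_group1.index,
        "logfc": res["logfc"],
        "moderated_t": res["t"],
        "p_value": res["p_value"],
        "adj_p_value": adj,
        "neg_log10_adj_p": neglog,
        "significant": (adj < adj_p_threshold) & (np.abs(res["logfc"]) > logfc_threshold),
    }).set_index("gene_id")


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up false-discovery-rate adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# Fisher exact / conditional-MLE odds ratio


@dataclass
class FisherResult:
    p_value: float
    odds_ratio: float  # conditional MLE; nan when a margin is zero
    table: ContingencyTable2x2


def _cmle_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Conditional MLE: solve E_psi[a | margins] = a on the Fisher noncentral
    hypergeometric model by bracketed root-finding on log psi."""
    total = a + b + c + d
    n_success = a + c      # column-1 margin
    n_draws = a + b        # row-1 margin
    support_min = max(0, n_draws - (total - n_success))
    support_max = min(n_draws, n_success)
    if a == support_min:
        return 0.0
    if a == support_max:
        return np.inf

    def mean_gap(log_psi: float) -> float:
        return sps.nchypergeom_fisher.mean(
            total, n_success, n_draws, np.exp(log_psi)) - a

    lo, hi = -1.0, 1.0
    while mean_gap(lo) > 0:
        lo *= 2
        if lo < -200:
            return 0.0
    while mean_gap(hi) < 0:
        hi *= 2
        if hi > 200:
            return np.inf
    return float(np.exp(brentq(mean_gap, lo, hi, xtol=1e-12, rtol=1e-14)))


def fisher_exact_2x2(table: ContingencyTable2x2) -> FisherResult:
    """Two-sided Fisher exact p with the conditional-MLE odds ratio.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed one. With a
    zero row or column margin the p-value is 1 and the odds ratio undefined
    (returned as nan).
    """
    arr = table.to_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        return FisherResult(p_value=1.0, odds_ratio=np.nan, table=table)
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    orr = _cmle_odds_ratio(table.a, table.b, table.c, table.d)
    return FisherResult(p_value=float(p), odds_ratio=orr, table=table)


# --------------------------------------------------------------------------
# mutation presence/absence classifier


def mutation_classifier_metrics(asd_carriers: int, asd_total: int,
                                td_carriers: int, td_total: int):
    """Diagnose by carrier status alone: carriers called cases.

    Cases with a risk-gene mutation are true positives, cases without are
    false negatives; controls with a mutation are false positives, controls
    without are true negatives. Precision is nan-signaled when no subject
    carries a mutation.
    """
    if asd_carriers > asd_total or td_carriers > td_total:
        raise ValueError("carrier counts exceed group totals")
    counts = ConfusionCounts(tp=asd_carriers, fn=asd_total - asd_carriers,
                             fp=td_carriers, tn=td_total - td_carriers)
    accuracy = (counts.tp + counts.tn) / counts.total
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else np.nan
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else np.nan
    return accuracy, precision, recall, counts


# --------------------------------------------------------------------------
# group comparisons


def welch_t(group1, group2) -> tuple[float, float, float]:
    """Welch's unequal-variance t with Satterthwaite df; returns (t, df, p)."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least 2 observations per group")
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if g1.mean() == g2.mean():
            return 0.0, float(len(g1) + len(g2) - 2), 1.0
        return np.inf * np.sign(g1.mean() - g2.mean()), float(len(g1) + len(g2) - 2), 0.0
    res = sps.ttest_ind(g1, g2, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def oneway_anova(groups) -> tuple[float, float, float, float]:
    """Classical one-way ANOVA; returns (F, df_between, df_within, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n_total = sum(len(g) for g in groups)
    df1 = len(groups) - 1
    df2 = n_total - len(groups)
    if df2 < 1:
        raise ValueError("not enough observations for within-group df")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*groups)
    if np.isnan(f):  # all groups identical and constant
        f, p = 0.0, 1.0
    return float(f), float(df1), float(df2), float(p)


def games_howell(groups: dict) -> pd.DataFrame:
    """Games-Howell pairwise comparisons for unequal-variance groups.

    Per pair: Welch-type standard error, Welch-Satterthwaite df, and
    q = |mean difference| * sqrt(2) / SE referred to the studentized-range
    distribution with k groups. The returned p-values are family-adjusted by
    that reference distribution.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrs = {g: np.asarray(groups[g], dtype=float) for g in names}
    for g, arr in arrs.items():
        if len(arr) < 2:
            raise ValueError(f"group {g!r} needs at least 2 observations")
    k = len(names)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrs[names[i]], arrs[names[j]]
            na, nb = len(a), len(b)
            va, vb = a.var(ddof=1), b.var(ddof=1)
            diff = a.mean() - b.mean()
            se2 = va / na + vb / nb
            if se2 == 0:
                q = 0.0 if diff == 0 else np.inf
                df = float(na + nb - 2)
                p = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(se2)
                df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
                q = np.abs(diff) * np.sqrt(2) / se
                p = float(sps.studentized_range.sf(q, k, df))
            rows.append({"group_a": names[i], "group_b": names[j],
                         "mean_diff": diff, "q": q, "df": df, "adj_p_value": p})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# age bins and the score ~ group * age regression

AGE_BIN_LABELS = ["0-20", "20-31", "31-49", ">49"]


def assign_age_bins(ages_months) -> pd.Categorical:
    """Fixed bins [0, 20), [20, 31), [31, 49]; older ages flagged ">49"."""
    ages = np.asarray(ages_months, dtype=float)
    if (ages < 0).any():
        raise ValueError("negative age")
    labels = np.select(
        [ages < 20, ages < 31, ages <= 49],
        AGE_BIN_LABELS[:3], default=AGE_BIN_LABELS[3])
    return pd.Categorical(labels, categories=AGE_BIN_LABELS, ordered=True)


def group_age_regression(scores, diagnoses, ages) -> pd.DataFrame:
    """OLS of score on group indicator, centered age, and their interaction."""
    import statsmodels.api as sm

    scores = np.asarray(scores, dtype=float)
    group = (np.asarray(diagnoses) == "ASD").astype(float)
    if group.min() == group.max():
        raise ValueError("both diagnostic groups must be present")
    age_c = np.asarray(ages, dtype=float)
    age_c = age_c - age_c.mean()
    design = pd.DataFrame({
        "group": group, "age": age_c, "group_x_age": group * age_c})
    x = sm.add_constant(design)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # name the degenerate column: first one whose removal restores rank
        for col in design.columns:
            reduced = x.drop(columns=[col])
            if np.linalg.matrix_rank(reduced.to_numpy()) == rank:
                raise ValueError(f"collinear design: column {col!r} is redundant")
        raise ValueError("collinear design")
    fit = sm.OLS(scores, x).fit()
    return pd.DataFrame({
        "coefficient": fit.params, "std_error": fit.bse,
        "t": fit.tvalues, "p_value": fit.pvalues})
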