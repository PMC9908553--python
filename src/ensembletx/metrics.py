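"""Ranking metrics: AUC-ROC and AUC-PR (average precision).

Both are computed from ranks, not from interpolated curves. AUC-ROC is the
Mann-Whitney pair statistic P(score_pos > score_neg) + 0.5 P(tie), so it is
invariant under any strictly increasing transform of the scores. AUC-PR uses
the average-precision convention: the sum over positives, taken in
score-descending order, of precision-at-that-rank times the recall increment,
with tied score groups processed as a block.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def _check(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return scores, labels.astype(int)


def auc_roc(scores, labels) -> float:
    """Mann-Whitney AUC; requires both classes present."""
    scores, labels = _check(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc_roc requires both classes present")
    ranks = rankdata(scores)  # midranks handle ties
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def auc_pr(scores, labels) -> float:
    """Average precision; requires at least one positive."""
    scores, labels = _check(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("auc_pr requires at least one positive")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]

    ap = 0.0
    tp = 0
    seen = 0
    i = 0
    n = len(y)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        block_pos = int(y[i:j].sum())
        tp += block_pos
        seen = j
        precision = tp / seen
        ap += precision * (block_pos / n_pos)
        i = j
    return float(ap)
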