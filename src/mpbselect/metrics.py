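"""Ranking metrics for imbalanced presence/absence prediction.

AUROC is the tie-averaged Mann-Whitney statistic: the probability that a
random positive outscores a random negative, counting ties as 1/2. AUPR uses
the step (average-precision) convention, sum over descending score
thresholds of (recall gain) * precision, with tied scores crossing the
threshold together. Under these conventions a constant classifier scores
exactly AUROC = 0.5 and AUPR = the positive prevalence — the null-model
reference values for each.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateResponseError


def _check(scores, labels, need_neg=True):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos + n_neg != labels.size:
        raise ValueError("labels must be 0/1")
    if n_pos == 0 or (need_neg and n_neg == 0):
        raise DegenerateResponseError("both classes required")
    return scores, labels, n_pos, n_neg


def auroc(scores, labels) -> float:
    """Area under the ROC curve (rank formulation, ties averaged)."""
    scores, labels, n_pos, n_neg = _check(scores, labels)
    ranks = rankdata(scores)  # average ranks handle ties
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (average precision)."""
    scores, labels, n_pos, _ = _check(scores, labels, need_neg=False)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order].astype(float)
    tp = np.cumsum(y)
    pred_pos = np.arange(1, len(y) + 1)
    # group tied scores: keep only the last index of each tie block
    last_of_block = np.nonzero(np.append(s[1:] != s[:-1], True))[0]
    recall = tp[last_of_block] / n_pos
    precision = tp[last_of_block] / pred_pos[last_of_block]
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - recall_prev) * precision))


def roc_curve(scores, labels) -> np.ndarray:
    """ROC points (FPR, TPR) from (0,0) to (1,1), tied scores grouped."""
    scores, labels, n_pos, n_neg = _check(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order].astype(float)
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    last_of_block = np.nonzero(np.append(s[1:] != s[:-1], True))[0]
    pts = np.column_stack([fp[last_of_block] / n_neg, tp[last_of_block] / n_pos])
    return np.vstack([[0.0, 0.0], pts])


def pr_curve(scores, labels) -> np.ndarray:
    """PR points (recall, precision) at descending score thresholds."""
    scores, labels, n_pos, _ = _check(scores, labels, need_neg=False)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order].astype(float)
    tp = np.cumsum(y)
    pred_pos = np.arange(1, len(y) + 1)
    last_of_block = np.nonzero(np.append(s[1:] != s[:-1], True))[0]
    return np.column_stack(
        [tp[last_of_block] / n_pos, tp[last_of_block] / pred_pos[last_of_block]]
    )
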