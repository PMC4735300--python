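"""Internal rank statistics shared by feature selection and model validation."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def rank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """All-pairs AUC via the Mann-Whitney rank identity.

    Equals the probability that a randomly chosen positive outscores a
    randomly chosen negative, with ties counted 1/2.  The rank-sum form is
    exactly equal to the explicit all-pairs enumeration (tied ranks are
    half-integers, representable in binary floating point).
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("rank_auc requires both a positive and a negative class")
    ranks = rankdata(scores)
    return float((ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(scores: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """ROC step curve as an (n_thresholds + 1, 2) array of (FPR, TPR).

    Thresholds sweep the distinct score values from high to low; the curve
    starts at (0, 0) and ends at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_points requires both a positive and a negative class")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = positive[order]
    tp = np.cumsum(sorted_pos)
    fp = np.cumsum(~sorted_pos)
    # keep only the last point at each distinct threshold
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = tp[distinct] / n_pos
    fpr = fp[distinct] / n_neg
    return np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])
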