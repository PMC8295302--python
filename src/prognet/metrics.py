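"""Classification metrics used across both pipeline stages."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def evaluate_auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    Equals the probability that a uniformly chosen positive outscores a
    uniformly chosen negative, with tied scores counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    rank_sum = ranks[pos].sum()
    u = rank_sum - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def evaluate_accuracy(scores, labels, threshold: float = 0.5) -> float:
    """Fraction of samples whose thresholded score matches the label."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = (scores >= threshold).astype(labels.dtype)
    return float((pred == labels).mean())
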