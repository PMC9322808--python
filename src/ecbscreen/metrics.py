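"""Ranking metrics shared by model evaluation and screening validation."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def auroc(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """AUROC via the rank-sum (Mann-Whitney) formulation, midrank ties.

    Equivalent to the probability that a random positive outscores a
    random negative, counting ties as 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    if scores.shape != is_positive.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(is_positive.sum())
    n_neg = int((~is_positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: need both positives and negatives")
    ranks = rankdata(scores)  # ascending midranks
    rank_sum = float(ranks[is_positive].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def enrichment_factor(
    ranked_positive_flags: np.ndarray, fraction: float
) -> float:
    """EF@f over flags ordered best-to-worst rank.

    (actives in top round(f*n) / round(f*n)) / (actives / n).
    """
    flags = np.asarray(ranked_positive_flags, dtype=bool)
    n = len(flags)
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    total = int(flags.sum())
    if total == 0 or total == n:
        raise ValueError("enrichment undefined without both classes")
    top = max(1, int(round(fraction * n)))
    return float((flags[:top].sum() / top) / (total / n))


def recall_at_k(ranked_positive_flags: np.ndarray, k: int) -> float:
    """Fraction of all actives found in the top k ranks."""
    flags = np.asarray(ranked_positive_flags, dtype=bool)
    total = int(flags.sum())
    if total == 0:
        raise ValueError("recall undefined with no actives")
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(flags[:k].sum()) / total
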