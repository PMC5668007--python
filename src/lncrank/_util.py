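"""Small shared numerics."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def rank_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """AUC by the rank-sum (Mann-Whitney) formulation; ties count one half."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))
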