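"""Rank-consensus selection of contrasts from per-fold attention weights.

Attention weights of highly intercorrelated contrasts differ only slightly
and their order fluctuates across cross-validation folds, so selection is
not read off a single ranking.  Instead, for increasing depth k the
candidate set S_k holds the contrasts ranked within the top k in *every*
fold; the procedure stops at the first k where S_k is non-empty and the sum
of the fold-averaged attention weights over S_k exceeds the threshold
(default 0.5, i.e. the selected contrasts jointly carry more than half of
the attention mass).  At k = n_contrasts every contrast qualifies and the
cumulative weight is 1, so the procedure always terminates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SelectionResult", "rank_contrasts", "consensus_select", "mean_attention_correct"]


@dataclass
class SelectionResult:
    selected: list[int]
    consensus_depth: int
    cumulative_weight: float
    per_fold_ranks: np.ndarray      # (n_folds, n_contrasts), rank 1 = largest
    mean_weights: np.ndarray        # fold-averaged attention weights

    def to_dict(self) -> dict:
        return {
            "selected": [int(i) for i in self.selected],
            "consensus_depth": int(self.consensus_depth),
            "cumulative_weight": float(self.cumulative_weight),
            "per_fold_ranks": self.per_fold_ranks.tolist(),
            "mean_weights": self.mean_weights.tolist(),
        }


def rank_contrasts(weights: np.ndarray) -> np.ndarray:
    """Ranks with 1 for the largest weight; ties broken by lower index."""
    w = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    order = np.lexsort((np.arange(len(w)), -w))  # descending weight, index tiebreak
    ranks = np.empty(len(w), dtype=int)
    ranks[order] = np.arange(1, len(w) + 1)
    return ranks


def consensus_select(per_fold_weights: np.ndarray, threshold: float = 0.5) -> SelectionResult:
    """Iterative rank-consensus selection (see module docstring)."""
    W = np.atleast_2d(np.asarray(per_fold_weights, dtype=float))
    n_folds, n_contrasts = W.shape
    if n_folds < 1:
        raise ValueError("need at least one fold")
    ranks = np.stack([rank_contrasts(w) for w in W])
    mean_w = W.mean(axis=0)
    for k in range(1, n_contrasts + 1):
        in_top_k = (ranks <= k).all(axis=0)
        if in_top_k.any():
            selected = np.flatnonzero(in_top_k)
            cum = float(mean_w[selected].sum())
            if cum > threshold:
                return SelectionResult(selected=[int(i) for i in selected],
                                       consensus_depth=k, cumulative_weight=cum,
                                       per_fold_ranks=ranks, mean_weights=mean_w)
    raise AssertionError("unreachable: S_k at k = n_contrasts has cumulative weight 1")


def mean_attention_correct(model, X_val: np.ndarray, y_val: np.ndarray,
                           threshold: float = 0.5) -> np.ndarray:
    """Mean attention vector over correctly predicted validation patches.

    The mean of simplex vectors lies on the simplex.  Raises if no patch is
    predicted correctly (an unusable fold).
    """
    if len(X_val) == 0:
        raise ValueError("validation set is empty")
    s = model.spec.spatial_size
    probs, attn = model.predict(X_val.reshape(len(X_val), model.spec.n_contrasts, s))
    correct = (probs >= threshold).astype(int) == np.asarray(y_val)
    if not correct.any():
        raise RuntimeError("no correctly predicted validation samples")
    return attn[correct].mean(axis=0)
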