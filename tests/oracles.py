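"""Independent brute-force oracles the implementation is checked against.

Everything here is deliberately naive — O(n*m) pair loops and per-voxel
iteration — so agreement with the vectorised implementations is meaningful.
"""

from __future__ import annotations

import numpy as np


def pairwise_p_hat(x, y) -> float:
    """Stochastic superiority P(X<Y) + 1/2 P(X=Y) by full pair enumeration."""
    wins = 0.0
    for xi in x:
        for yj in y:
            if xi < yj:
                wins += 1.0
            elif xi == yj:
                wins += 0.5
    return wins / (len(x) * len(y))


def pairwise_auc(scores, labels) -> float:
    """Binary AUC via the all-pairs Mann-Whitney loop with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def pairwise_ordinal_concordance(scores, levels) -> float:
    """Concordance over all pairs with different outcome levels (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    levels = np.asarray(levels)
    num = 0.0
    den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(i + 1, n):
            if levels[i] == levels[j]:
                continue
            den += 1.0
            hi, lo = (i, j) if levels[i] > levels[j] else (j, i)
            if scores[hi] > scores[lo]:
                num += 1.0
            elif scores[hi] == scores[lo]:
                num += 0.5
    return num / den


def voxel_loop_decompose(mask_values, labels, relevance_map) -> dict:
    """Per-voxel loop attribution of lesion voxels to relevance classes."""
    counts = {"high": 0, "moderate": 0, "low": 0, "unclassified": 0, "total": 0}
    it = np.ndindex(mask_values.shape)
    for idx in it:
        if not mask_values[idx]:
            continue
        counts["total"] += 1
        rid = int(labels[idx])
        cls = "unclassified" if rid == 0 else relevance_map[rid]
        counts[cls] += 1
    return counts
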