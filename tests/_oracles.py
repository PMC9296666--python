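"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths: the rank-sum oracle
enumerates group assignments and computes the Mann-Whitney U by pairwise
greater-than counting; the agglomeration oracle merges clusters naively
from a full distance matrix.
"""

from __future__ import annotations

import itertools

import numpy as np


def exact_rank_sum_p(x, y) -> float:
    """Two-sided exact permutation p-value via pairwise U counting.

    For every assignment of the pooled values into groups of the observed
    sizes, U = #{(i in A, j in B): v_i > v_j} + 0.5 #{ties}. The two-sided
    p doubles the smaller tail of the permutation distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n = pooled.size
    n1 = x.size
    # G[i, j] = score of value i beating value j
    G = (pooled[:, None] > pooled[None, :]).astype(float)
    G += 0.5 * (pooled[:, None] == pooled[None, :])
    np.fill_diagonal(G, 0.0)

    combos = np.array(list(itertools.combinations(range(n), n1)))
    M = np.zeros((len(combos), n), dtype=float)
    np.put_along_axis(M, combos, 1.0, axis=1)
    # U per assignment: sum over i in group, j out of group of G[i, j]
    dist = ((M @ G) * (1.0 - M)).sum(axis=1)
    obs = ((pooled[:n1, None] > pooled[None, n1:]).sum()
           + 0.5 * (pooled[:n1, None] == pooled[None, n1:]).sum())
    eps = 1e-9
    p_low = np.mean(dist <= obs + eps)
    p_high = np.mean(dist >= obs - eps)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def naive_average_linkage(points: np.ndarray):
    """Naive agglomeration with average linkage on euclidean distances.

    Returns the sequence of (merged_pair_as_frozensets, height) in merge
    order, where heights are the mean pairwise distance between the two
    merged clusters' members.
    """
    n = len(points)
    clusters = [frozenset([i]) for i in range(n)]
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or dist < best[0] - 1e-12:
                best = (dist, a, b)
        dist, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((frozenset([clusters[a], clusters[b]]), dist))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


def cluster_mean(dense: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean over a cell mask, the long way (per-gene loop)."""
    return np.array([dense[g, mask].mean() for g in range(dense.shape[0])])
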