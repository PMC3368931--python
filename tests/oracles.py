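"""Independent brute-force oracles used to validate the implementations.

Everything here deliberately avoids the production code paths: the spike
metric oracle enumerates all injective partial matchings between two
trains, the clustering oracle searches all exemplar subsets, and the
UPGMA oracle agglomerates by direct averaging over original distances.
"""

from __future__ import annotations

import itertools

import numpy as np


def vp_oracle(a, b, q):
    """Minimal edit cost by exhaustive enumeration of partial matchings.

    Every one-to-one pairing between a subset of a's spikes and a subset
    of b's spikes (not restricted to order-preserving ones) is scored as
    (unmatched spikes) + q * sum |dt| over matched pairs.
    """
    a = list(a)
    b = list(b)
    best = float(len(a) + len(b))
    for k in range(1, min(len(a), len(b)) + 1):
        for sa in itertools.combinations(range(len(a)), k):
            for sb in itertools.permutations(range(len(b)), k):
                cost = (len(a) - k) + (len(b) - k) + sum(
                    q * abs(a[i] - b[j]) for i, j in zip(sa, sb)
                )
                best = min(best, cost)
    return best


def bsd_oracle(a, b, q, n_max):
    """Burst-shift distance via vp_oracle over all initial-deletion counts."""
    a = list(a)
    b = list(b)
    best = float("inf")
    for ka in range(min(n_max, len(a)) + 1):
        ra = [t - a[ka] for t in a[ka:]] if ka < len(a) else []
        for kb in range(min(n_max, len(b)) + 1):
            rb = [t - b[kb] for t in b[kb:]] if kb < len(b) else []
            best = min(best, ka + kb + vp_oracle(ra, rb, q))
    return best


def net_similarity(S, exemplars, assignment):
    """Affinity-propagation objective: sum of similarities to exemplars
    plus the preferences of the chosen exemplars."""
    total = sum(S[k, k] for k in exemplars)
    for i, e in enumerate(assignment):
        if i not in exemplars:
            total += S[i, e]
    return total


def best_exemplar_subset(S):
    """Exhaustive maximizer of the net-similarity objective (n <= ~15)."""
    n = S.shape[0]
    best_score, best_set = -np.inf, None
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            ex = np.array(subset)
            assign = ex[np.argmax(S[:, ex], axis=1)]
            assign[ex] = ex
            score = net_similarity(S, set(subset), assign)
            if score > best_score:
                best_score, best_set = score, set(subset)
    return best_set, best_score


def upgma_heights(D):
    """Merge heights of group-average agglomeration, computed directly.

    Cluster-to-cluster distance is the mean of all original pairwise
    distances between their members.
    """
    D = np.asarray(D, dtype=float)
    clusters = [[i] for i in range(D.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for x, y in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([D[i, j] for i in clusters[x] for j in clusters[y]])
            if d < best[0]:
                best = (d, (x, y))
        d, (x, y) = best
        heights.append(d)
        merged = clusters[x] + clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(merged)
    return np.array(heights)


def entropy_bits(p):
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def random_train(rng, n_max=5, t_max=0.1):
    """Sorted random spike train with 0..n_max spikes."""
    n = int(rng.integers(0, n_max + 1))
    return np.sort(rng.uniform(0.0, t_max, size=n))


def random_burst_train(rng, n_min=5, n_max=12):
    """Onset-relative burst-like train (first spike at 0, ISIs 2-15 ms)."""
    n = int(rng.integers(n_min, n_max + 1))
    isis = rng.uniform(0.002, 0.015, size=n - 1)
    return np.concatenate([[0.0], np.cumsum(isis)])
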