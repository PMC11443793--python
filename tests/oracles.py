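"""Naive reference implementations used as independent oracles.

Everything here is deliberately written as explicit Python loops over
instances and features, independent of the vectorized code paths under
test.  Complexity is O(m^2 n) or worse; keep inputs tiny.
"""

import numpy as np


def naive_distance(X):
    m = X.shape[0]
    D = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(m):
            D[i, j] = sum(1 for f in range(X.shape[1]) if X[i, f] != X[j, f])
    return D


def naive_relieff(X, y, nn):
    """ReliefF by explicit neighbor lists; ties break by ascending index."""
    m, n = X.shape
    D = naive_distance(X)
    scores = np.zeros(n)
    for t in range(m):
        hits = sorted(
            (j for j in range(m) if j != t and y[j] == y[t]),
            key=lambda j: (D[t, j], j),
        )
        misses = sorted(
            (j for j in range(m) if y[j] != y[t]), key=lambda j: (D[t, j], j)
        )
        kh = min(nn, len(hits))
        km = min(nn, len(misses))
        for f in range(n):
            hit_diff = sum(1 for j in hits[:kh] if X[j, f] != X[t, f])
            miss_diff = sum(1 for j in misses[:km] if X[j, f] != X[t, f])
            term = 0.0
            if km:
                term += miss_diff / km
            if kh:
                term -= hit_diff / kh
            scores[f] += term
    return scores / m


def naive_partition(X, target, deadband_multiplier=0.5):
    """Near/far index sets around one target from first principles."""
    D = naive_distance(X)
    others = [j for j in range(X.shape[0]) if j != target]
    d = np.array([D[target, j] for j in others], dtype=float)
    T = d.mean()
    band = deadband_multiplier * d.std()
    near = [j for j in others if D[target, j] < T - band]
    far = [j for j in others if D[target, j] > T + band]
    return near, far, T, band


def _mean_mismatch(X, t, members, f):
    if not members:
        return 0.0
    return sum(1 for j in members if X[j, f] != X[t, f]) / len(members)


def naive_multisurf(X, y, deadband_multiplier=0.5):
    m, n = X.shape
    scores = np.zeros(n)
    for t in range(m):
        near, _, _, _ = naive_partition(X, t, deadband_multiplier)
        near_hits = [j for j in near if y[j] == y[t]]
        near_miss = [j for j in near if y[j] != y[t]]
        for f in range(n):
            scores[f] += _mean_mismatch(X, t, near_miss, f) - _mean_mismatch(
                X, t, near_hits, f
            )
    return scores / m


def naive_multisurfstar(X, y, deadband_multiplier=0.5):
    m, n = X.shape
    scores = np.zeros(n)
    for t in range(m):
        near, far, _, _ = naive_partition(X, t, deadband_multiplier)
        near_hits = [j for j in near if y[j] == y[t]]
        near_miss = [j for j in near if y[j] != y[t]]
        far_hits = [j for j in far if y[j] == y[t]]
        far_miss = [j for j in far if y[j] != y[t]]
        for f in range(n):
            near_term = _mean_mismatch(X, t, near_miss, f) - _mean_mismatch(
                X, t, near_hits, f
            )
            far_term = _mean_mismatch(X, t, far_hits, f) - _mean_mismatch(
                X, t, far_miss, f
            )
            scores[f] += 0.5 * (near_term + far_term)
    return scores / m


def random_dataset(rng, m, n, ensure_both_classes=True):
    """Small random genotype dataset for oracle comparisons."""
    X = rng.integers(0, 3, size=(m, n)).astype(np.int8)
    while True:
        y = rng.integers(0, 2, size=m).astype(np.int8)
        counts = np.bincount(y, minlength=2)
        if not ensure_both_classes or counts.min() >= 2:
            return X, y
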