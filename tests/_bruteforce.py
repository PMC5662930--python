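"""Exhaustive-enumeration oracles for small segmentation problems.

Everything here is written independently of the package's dynamic-programming
code paths: segmentations are enumerated explicitly and posterior quantities
are tallied in probability space, so these functions serve as ground truth
for series short enough to enumerate (T <= ~15).
"""

from itertools import combinations

import numpy as np


def enumerate_segmentations(T, n_segments, min_len):
    """Yield all change-point tuples (0-based first cells of later segments)."""
    if n_segments == 1:
        if T >= min_len:
            yield ()
        return
    for taus in combinations(range(1, T), n_segments - 1):
        bounds = (0, *taus, T)
        if all(bounds[i + 1] - bounds[i] >= min_len for i in range(n_segments)):
            yield taus


def loglik_of(cost, taus, T):
    bounds = (0, *taus, T)
    return sum(cost[bounds[i], bounds[i + 1] - 1] for i in range(len(bounds) - 1))


def ranked_segmentations(cost, n_segments, min_len):
    """All feasible segmentations sorted by log-likelihood (desc), ties by
    lexicographic change-point order."""
    T = cost.shape[0]
    items = [
        (taus, loglik_of(cost, taus, T))
        for taus in enumerate_segmentations(T, n_segments, min_len)
    ]
    items.sort(key=lambda it: (-it[1], it[0]))
    return items


def evidence(cost, n_segments, min_len):
    ranked = ranked_segmentations(cost, n_segments, min_len)
    lls = np.array([ll for _, ll in ranked])
    m = lls.max()
    return m + np.log(np.exp(lls - m).sum())


def posteriors(cost, n_segments, min_len):
    """(segmentations, posterior weights) over the whole space."""
    ranked = ranked_segmentations(cost, n_segments, min_len)
    lls = np.array([ll for _, ll in ranked])
    w = np.exp(lls - lls.max())
    return [taus for taus, _ in ranked], w / w.sum()


def zone_occupancy(cost, n_segments, min_len):
    T = cost.shape[0]
    segs, w = posteriors(cost, n_segments, min_len)
    occ = np.zeros((T, n_segments))
    for taus, weight in zip(segs, w):
        bounds = (0, *taus, T)
        for j in range(n_segments):
            occ[bounds[j] : bounds[j + 1], j] += weight
    return occ


def changepoint_posteriors(cost, n_segments, min_len):
    T = cost.shape[0]
    segs, w = posteriors(cost, n_segments, min_len)
    P = np.zeros((n_segments - 1, T))
    for taus, weight in zip(segs, w):
        for j, tau in enumerate(taus):
            P[j, tau] += weight
    return P


def max_assignment_profiles(cost, n_segments, min_len):
    T = cost.shape[0]
    segs, w = posteriors(cost, n_segments, min_len)
    M = np.zeros((T, n_segments))
    for taus, weight in zip(segs, w):
        bounds = (0, *taus, T)
        for j in range(n_segments):
            sl = slice(bounds[j], bounds[j + 1])
            M[sl, j] = np.maximum(M[sl, j], weight)
    return M
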