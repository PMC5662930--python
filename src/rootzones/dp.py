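"""Generic multiple change-point machinery over a precomputed segment-cost matrix.

Everything here works on a ``cost`` matrix where ``cost[u, v]`` is the maximised
segment log-likelihood of cells ``u..v`` (0-based, inclusive) under some
within-segment model, with ``-inf`` marking infeasible segments (shorter than
the minimum segment length).  The model families (piecewise linear, change in
the variance) only differ in how this matrix is built, so dynamic programming,
N-best enumeration and the forward-backward sums over the whole segmentation
space are shared.

Indices: a segmentation of ``T`` cells into ``J`` segments is encoded by its
change points ``tau_1 < ... < tau_{J-1}``, each the 0-based index of the first
cell of the shootward segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "InfeasibleSegmentationError",
    "optimal_changepoints",
    "top_changepoints",
    "log_evidence",
    "forward_log",
    "backward_log",
    "changepoint_posteriors",
    "zone_occupancy",
    "max_assignment_profiles",
    "credible_interval",
]


class InfeasibleSegmentationError(ValueError):
    """Raised when T, J and the minimum segment length admit no segmentation."""


def _check_feasible(cost: np.ndarray, n_segments: int, min_len: int) -> int:
    T = cost.shape[0]
    if n_segments < 1:
        raise InfeasibleSegmentationError("need at least one segment")
    if n_segments * min_len > T:
        raise InfeasibleSegmentationError(
            f"cannot place {n_segments} segments of >= {min_len} cells in T={T}"
        )
    return T


def _suffix_values(cost: np.ndarray, n_segments: int) -> np.ndarray:
    """S[j, u] = max log-likelihood of segmenting u..T-1 into j+1 segments."""
    T = cost.shape[0]
    S = np.full((n_segments, T), -np.inf)
    S[0] = cost[:, T - 1]
    for j in range(1, n_segments):
        # segment starts at u, ends at v; remainder v+1..T-1 takes j segments
        prev = S[j - 1]
        for u in range(T):
            vals = cost[u, u : T - 1] + prev[u + 1 : T]
            if vals.size:
                S[j, u] = np.max(vals)
    return S


def optimal_changepoints(
    cost: np.ndarray, n_segments: int, min_len: int = 1
) -> tuple[np.ndarray, float]:
    """Most likely segmentation for a fixed number of segments.

    Returns the change-point vector (length ``n_segments - 1``) and its total
    log-likelihood.  Among co-optimal segmentations the lexicographically
    smallest change-point vector is returned, which makes the output
    deterministic.
    """
    T = _check_feasible(cost, n_segments, min_len)
    S = _suffix_values(cost, n_segments)
    total = S[n_segments - 1, 0]
    if not np.isfinite(total):
        raise InfeasibleSegmentationError("no feasible segmentation")
    taus = []
    u = 0
    for j in range(n_segments - 1, 0, -1):
        # smallest v whose split attains the optimum -> lexicographic min taus
        vals = cost[u, u : T - 1] + S[j - 1, u + 1 : T]
        v = int(np.flatnonzero(vals == S[j, u])[0]) + u
        taus.append(v + 1)
        u = v + 1
    return np.asarray(taus, dtype=int), float(total)


def top_changepoints(
    cost: np.ndarray, n_segments: int, n_best: int, min_len: int = 1
) -> list[tuple[np.ndarray, float]]:
    """The ``n_best`` highest-likelihood segmentations, strictly ordered.

    Ties in log-likelihood are broken by lexicographic order of the
    change-point vectors.  Fewer than ``n_best`` segmentations are returned
    when the feasible space is smaller.
    """
    T = _check_feasible(cost, n_segments, min_len)
    if n_best < 1:
        raise ValueError("n_best must be >= 1")
    J, N = n_segments, n_best
    # B[j][t]: top-N values of segmenting 0..t into j+1 segments, with
    # backpointers (previous segment end, rank at that state).
    vals = np.full((J, T, N), -np.inf)
    back = np.full((J, T, N, 2), -1, dtype=int)
    vals[0, :, 0] = cost[0, :]
    for j in range(1, J):
        prev = vals[j - 1]  # (T, N)
        for t in range(T):
            cand = prev[: t, :] + cost[1 : t + 1, t][:, None]
            flat = cand.ravel()
            if flat.size == 0:
                continue
            k = min(N, flat.size)
            idx = np.argpartition(flat, -k)[-k:]
            idx = idx[np.argsort(flat[idx])[::-1]]
            kept = flat[idx]
            finite = np.isfinite(kept)
            idx, kept = idx[finite], kept[finite]
            vals[j, t, : idx.size] = kept
            back[j, t, : idx.size, 0] = idx // N  # previous segment end u
            back[j, t, : idx.size, 1] = idx % N  # rank at (j-1, u)
    out: list[tuple[np.ndarray, float]] = []
    for r in range(N):
        v = vals[J - 1, T - 1, r]
        if not np.isfinite(v):
            break
        taus = []
        t, rank = T - 1, r
        for j in range(J - 1, 0, -1):
            u, rank = back[j, t, rank]
            taus.append(u + 1)
            t = u
        out.append((np.asarray(taus[::-1], dtype=int), float(v)))
    out.sort(key=lambda item: (-item[1], item[0].tolist()))
    return out


def forward_log(cost: np.ndarray, n_segments: int) -> np.ndarray:
    """F[j, t] = log sum of likelihoods of segmenting 0..t into j+1 segments
    with segment j ending exactly at t."""
    T = cost.shape[0]
    F = np.full((n_segments, T), -np.inf)
    F[0] = cost[0, :]
    with np.errstate(invalid="ignore"):
        for j in range(1, n_segments):
            prev = F[j - 1]
            for t in range(T):
                if t == 0:
                    continue
                F[j, t] = logsumexp(prev[:t] + cost[1 : t + 1, t])
    return F


def backward_log(cost: np.ndarray, n_segments: int) -> np.ndarray:
    """G[j, u] = log sum of likelihoods of segmenting u..T-1 into the last
    ``n_segments - j`` segments, with segment j starting exactly at u."""
    T = cost.shape[0]
    G = np.full((n_segments, T), -np.inf)
    G[n_segments - 1] = cost[:, T - 1]
    with np.errstate(invalid="ignore"):
        for j in range(n_segments - 2, -1, -1):
            nxt = G[j + 1]
            for u in range(T):
                vals = cost[u, u : T - 1] + nxt[u + 1 : T]
                if vals.size:
                    G[j, u] = logsumexp(vals)
    return G


def log_evidence(cost: np.ndarray, n_segments: int, min_len: int = 1) -> float:
    """log of the likelihood summed over every feasible segmentation."""
    _check_feasible(cost, n_segments, min_len)
    value = forward_log(cost, n_segments)[n_segments - 1, cost.shape[0] - 1]
    if not np.isfinite(value):
        raise InfeasibleSegmentationError("no feasible segmentation")
    return float(value)


@dataclass(frozen=True)
class _FB:
    forward: np.ndarray
    backward: np.ndarray
    log_evidence: float


def _fb(cost: np.ndarray, n_segments: int, min_len: int) -> _FB:
    _check_feasible(cost, n_segments, min_len)
    F = forward_log(cost, n_segments)
    G = backward_log(cost, n_segments)
    lz = F[n_segments - 1, cost.shape[0] - 1]
    if not np.isfinite(lz):
        raise InfeasibleSegmentationError("no feasible segmentation")
    return _FB(F, G, float(lz))


def changepoint_posteriors(
    cost: np.ndarray, n_segments: int, min_len: int = 1
) -> np.ndarray:
    """P[j-1, t] = posterior probability that change point j sits at cell t.

    Row ``j-1`` is the distribution of ``tau_j`` (first cell of segment j,
    1-based j in ``1..J-1``) over cell indices; each row sums to one.
    """
    fb = _fb(cost, n_segments, min_len)
    T = cost.shape[0]
    P = np.zeros((n_segments - 1, T))
    for j in range(1, n_segments):
        with np.errstate(invalid="ignore"):
            logp = np.full(T, -np.inf)
            logp[1:] = fb.forward[j - 1, : T - 1] + fb.backward[j, 1:] - fb.log_evidence
        P[j - 1] = np.exp(logp)
        P[j - 1] /= P[j - 1].sum()
    return P


def zone_occupancy(cost: np.ndarray, n_segments: int, min_len: int = 1) -> np.ndarray:
    """O[t, j] = posterior probability that cell t belongs to segment j.

    Cell t lies in segment j exactly when ``tau_j <= t < tau_{j+1}``, so the
    occupancy is a difference of change-point posterior CDFs; rows sum to one.
    """
    T = cost.shape[0]
    P = changepoint_posteriors(cost, n_segments, min_len)
    cdf = np.ones((n_segments + 1, T))
    cdf[n_segments] = 0.0
    for j in range(1, n_segments):
        cdf[j] = np.cumsum(P[j - 1])
    occ = (cdf[:-1] - cdf[1:]).T
    return occ


def max_assignment_profiles(
    cost: np.ndarray, n_segments: int, min_len: int = 1
) -> np.ndarray:
    """M[t, j] = the highest posterior probability of any single segmentation
    that assigns cell t to segment j (max-type analogue of the occupancy)."""
    fb = _fb(cost, n_segments, min_len)
    T, J = cost.shape[0], n_segments
    # Viterbi-style max analogues of the forward/backward sums.
    Fm = np.full((J, T), -np.inf)
    Fm[0] = cost[0, :]
    for j in range(1, J):
        for t in range(1, T):
            vals = Fm[j - 1, :t] + cost[1 : t + 1, t]
            Fm[j, t] = np.max(vals, initial=-np.inf)
    Gm = np.full((J, T), -np.inf)
    Gm[J - 1] = cost[:, T - 1]
    for j in range(J - 2, -1, -1):
        for u in range(T):
            vals = cost[u, u : T - 1] + Gm[j + 1, u + 1 : T]
            Gm[j, u] = np.max(vals, initial=-np.inf)
    M = np.full((T, J), -np.inf)
    for j in range(J):
        if j == 0:
            A = np.full(T, -np.inf)
            A[0] = 0.0
        else:
            A = np.full(T, -np.inf)
            A[1:] = Fm[j - 1, : T - 1]  # A[u] = best prefix ending at u-1
        if j == J - 1:
            B = np.full(T, -np.inf)
            B[T - 1] = 0.0
        else:
            B = np.full(T, -np.inf)
            B[: T - 1] = Gm[j + 1, 1:]  # B[v] = best suffix starting at v+1
        col = np.full(T, -np.inf)
        for u in range(T):
            if A[u] == -np.inf:
                continue
            vals = A[u] + cost[u, :] + B  # over segment ends v
            # best over v >= t for every t >= u: suffix running max
            suff = np.maximum.accumulate(vals[::-1])[::-1]
            col[u:] = np.maximum(col[u:], suff[u:])
        M[:, j] = np.exp(col - fb.log_evidence)
    return M


def credible_interval(
    pmf: np.ndarray, map_index: int, coverage: float = 0.95
) -> tuple[int, int]:
    """Smallest contiguous index interval around ``map_index`` with mass
    >= ``coverage``, grown greedily toward the heavier side (ties rootward)."""
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    pmf = np.asarray(pmf, dtype=float)
    if pmf[map_index] <= 0:
        raise ValueError("map_index carries no posterior mass")
    support = np.flatnonzero(pmf > 0)
    lo = hi = int(map_index)
    mass = pmf[map_index]
    total = pmf.sum()
    while mass < coverage * total - 1e-12:
        left = pmf[lo - 1] if lo - 1 >= support[0] else -1.0
        right = pmf[hi + 1] if hi + 1 <= support[-1] else -1.0
        if left < 0 and right < 0:
            break
        if left >= right:
            lo -= 1
            mass += pmf[lo]
        else:
            hi += 1
            mass += pmf[hi]
    return lo, hi
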