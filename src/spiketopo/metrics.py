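"""Victor-Purpura spike-train metric, distance matrices, and rank-order transform.

The Victor-Purpura (VP) distance between two spike trains is the minimum
total cost of editing one train into the other using three moves: insert a
spike (cost 1), delete a spike (cost 1), shift a spike by time t (cost q*t).
It is computed by the standard dynamic program

    G[i][j] = min(G[i-1][j] + 1, G[i][j-1] + 1, G[i-1][j-1] + q*|t_i - s_j|),

with G[i][0] = i and G[0][j] = j.  As q -> 0 the distance degenerates to the
spike-count difference |n - m|; large q makes any shift more expensive than
delete+insert, so 1/q is the temporal precision at which the metric treats
spikes as coincident.

A distance matrix over all neuron pairs is then converted to the normalized
rank-ordered matrix M: above-diagonal distances are replaced by their ranks,
mirrored below the diagonal, divided by N(N-1)/2, and the rows/columns are
permuted in descending order of per-neuron firing rate.  Under the default
convention the *largest* distance receives rank 0, so larger D_ij means
smaller M_ij (closeness matrix); the literal ascending convention is also
available.  M is invariant under any strictly monotone transform of D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "SpikeTrain",
    "DistanceMatrix",
    "RankMatrix",
    "vp_distance",
    "distance_matrix",
    "rank_order",
    "firing_rate",
    "select_top_active",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative VP distance matrix with its shift cost q (s^-1)."""

    D: np.ndarray
    q: float


@dataclass(frozen=True)
class RankMatrix:
    """Normalized rank-ordered matrix M and the rate-descending neuron order.

    ``neuron_order[k]`` is the original index of the neuron placed at row k.
    Diagonal entries take the convention-consistent extreme (1 under the
    default descending convention: a neuron is maximally close to itself);
    the diagonal is excluded from ranking.
    """

    M: np.ndarray
    neuron_order: np.ndarray
    convention: str = "descending"


def _as_train(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("spike train must be one-dimensional")
    if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
        raise ValueError("spike train must be non-negative and strictly increasing")
    return t


@njit(cache=True)
def _vp_dp(a: np.ndarray, b: np.ndarray, q: float) -> float:
    n, m = len(a), len(b)
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    for j in range(m + 1):
        prev[j] = j
    for i in range(1, n + 1):
        cur[0] = i
        ai = a[i - 1]
        for j in range(1, m + 1):
            shift = prev[j - 1] + q * abs(ai - b[j - 1])
            ins = cur[j - 1] + 1.0
            dele = prev[j] + 1.0
            best = shift
            if ins < best:
                best = ins
            if dele < best:
                best = dele
            cur[j] = best
        prev, cur = cur, prev
    return prev[m]


def vp_distance(a, b, q: float = 1.0) -> float:
    """VP distance between two sorted spike trains (times in s, q in s^-1)."""
    if q < 0:
        raise ValueError("cost q must be non-negative")
    ta, tb = _as_train(a), _as_train(b)
    if ta.size == 0 or tb.size == 0:
        return float(ta.size + tb.size)
    return float(_vp_dp(ta, tb, q))


@njit(cache=True)
def _vp_matrix(flat: np.ndarray, offsets: np.ndarray, q: float) -> np.ndarray:
    n = len(offsets) - 1
    D = np.zeros((n, n))
    for i in range(n):
        a = flat[offsets[i] : offsets[i + 1]]
        for j in range(i + 1, n):
            b = flat[offsets[j] : offsets[j + 1]]
            if len(a) == 0 or len(b) == 0:
                d = float(len(a) + len(b))
            else:
                d = _vp_dp(a, b, q)
            D[i, j] = d
            D[j, i] = d
    return D


def distance_matrix(trains, q: float = 1.0) -> DistanceMatrix:
    """Pairwise VP distances over a list of spike trains (computed once per pair)."""
    trains = [_as_train(t) for t in trains]
    if len(trains) < 2:
        raise ValueError("need at least 2 spike trains")
    offsets = np.zeros(len(trains) + 1, dtype=np.int64)
    offsets[1:] = np.cumsum([len(t) for t in trains])
    flat = np.concatenate(trains) if offsets[-1] else np.zeros(0)
    return DistanceMatrix(D=_vp_matrix(flat, offsets, q), q=q)


def firing_rate(train, T: float) -> float:
    """Mean firing rate in Hz: spike count divided by trial length."""
    if T <= 0:
        raise ValueError("T must be positive")
    return len(_as_train(train)) / T


def select_top_active(rates, k: int) -> np.ndarray:
    """Indices of the k most active neurons, rates descending.

    Ties are broken in favor of the lower neuron index.
    """
    rates = np.asarray(rates, dtype=float)
    if not 1 <= k <= len(rates):
        raise ValueError("require 1 <= k <= number of neurons")
    order = np.lexsort((np.arange(len(rates)), -rates))
    return order[:k]


def rank_order(
    D: DistanceMatrix | np.ndarray,
    rates,
    convention: str = "descending",
) -> RankMatrix:
    """Rank-order and normalize a distance matrix, reindexed by firing rate.

    convention="descending" (default): the largest distance gets rank 0, so
    more distant pairs get smaller entries of M.  convention="ascending":
    the smallest distance gets rank 0.  Either way entries lie in
    [0, (K-1)/K] with K = N(N-1)/2 and exact ties in D are broken by
    lexicographic (i, j) order of the pair.
    """
    Dm = D.D if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    if Dm.ndim != 2 or Dm.shape[0] != Dm.shape[1]:
        raise ValueError("D must be square")
    if np.any(np.isnan(Dm)):
        raise ValueError("NaN entries in distance matrix")
    if convention not in ("descending", "ascending"):
        raise ValueError("convention must be 'descending' or 'ascending'")
    n = Dm.shape[0]
    rates = np.asarray(rates, dtype=float)
    if len(rates) != n:
        raise ValueError("rates length must match matrix size")

    iu, ju = np.triu_indices(n, k=1)
    vals = Dm[iu, ju]
    K = vals.size
    # stable sort on value with (i, j) as implicit tie-break (triu order is lexicographic)
    if convention == "descending":
        order = np.argsort(-vals, kind="stable")
    else:
        order = np.argsort(vals, kind="stable")
    ranks = np.empty(K, dtype=float)
    ranks[order] = np.arange(K, dtype=float)

    M = np.zeros((n, n))
    M[iu, ju] = ranks / K
    M += M.T
    np.fill_diagonal(M, 1.0 if convention == "descending" else 0.0)

    perm = select_top_active(rates, n)
    M = M[np.ix_(perm, perm)]
    return RankMatrix(M=M, neuron_order=perm, convention=convention)
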