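"""Vietoris-Rips persistent homology (dimensions 0 and 1) of a dissimilarity matrix.

The filtration parameter rho sweeps [0, max M]; vertices are present from
rho = 0, the edge (i, j) enters at rho = M_ij, and a triangle enters at the
largest of its three edge values (clique/flag rule).  Homology is computed
over the two-element field GF(2).

* Dimension 0: Kruskal-style union-find over edges sorted by weight.  Each of
  the n vertices contributes a bar born at 0; a merging (MST) edge kills one
  bar at its weight, leaving exactly one infinite bar.
* Dimension 1: boundary-matrix reduction of triangle columns over the edge
  basis, with columns held as Python integer bitmasks (XOR = GF(2) addition,
  highest set bit = pivot).  A reduced triangle column pairs its pivot edge
  (the cycle's birth) with the triangle (its death).  In a full clique complex
  every 1-cycle eventually dies, so there are no infinite bars in dimension 1.

Dimension-1 bars of zero persistence (birth == death) are dropped by
default, as is standard for barcode output; dimension 0 keeps one bar per
vertex so a plotted barcode always starts from n bars.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import inf

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc

__all__ = [
    "PersistenceBar",
    "BettiCurve",
    "rips_persistence",
    "betti_curve",
    "connected_components_at",
]


@dataclass(frozen=True)
class PersistenceBar:
    """One barcode interval: homology dimension, birth and death filtration values."""

    dim: int
    birth: float
    death: float  # math.inf for essential classes

    def __post_init__(self) -> None:
        if self.death < self.birth:
            raise ValueError("bar death must not precede birth")


@dataclass
class BettiCurve:
    """Betti number beta_dim evaluated on an ascending grid of rho values."""

    grid: np.ndarray
    counts: np.ndarray
    dim: int


def _validated(M) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be a square matrix")
    if not np.all(np.isfinite(M)):
        raise ValueError("M must be finite")
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValueError("M must be symmetric")
    return M


def _sorted_edges(M: np.ndarray) -> list[tuple[float, int, int]]:
    n = M.shape[0]
    return sorted((M[i, j], i, j) for i in range(n) for j in range(i + 1, n))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def rips_persistence(
    M, max_dim: int = 1, *, keep_zero_bars: bool = False
) -> list[PersistenceBar]:
    """Persistence barcode of the Vietoris-Rips filtration of a dissimilarity matrix.

    The diagonal of M is ignored (a vertex is present from rho = 0 regardless).
    Dimension 0 always yields exactly n bars born at 0 (one per vertex, the
    essential one with infinite death); dimension-1 bars of zero persistence
    are dropped unless ``keep_zero_bars`` is set.  Returns bars sorted by
    (dim, birth, death).
    """
    M = _validated(M)
    n = M.shape[0]
    if max_dim not in (0, 1):
        raise ValueError("only dimensions 0 and 1 are supported")
    edges = _sorted_edges(M)

    # dimension 0: one bar per vertex (zero-persistence merges retained so the
    # barcode always shows n bars born at rho = 0, as in a plotted barcode)
    bars: list[PersistenceBar] = []
    uf = _UnionFind(n)
    n_merged = 0
    for w, i, j in edges:
        if uf.union(i, j):
            n_merged += 1
            bars.append(PersistenceBar(0, 0.0, w))
    for _ in range(n - n_merged):
        bars.append(PersistenceBar(0, 0.0, inf))

    if max_dim >= 1 and n >= 3:
        bars.extend(_h1_bars(M, edges, keep_zero_bars))

    bars.sort(key=lambda b: (b.dim, b.birth, b.death))
    return bars


def _h1_bars(
    M: np.ndarray, edges: list[tuple[float, int, int]], keep_zero_bars: bool
) -> list[PersistenceBar]:
    """Reduce the triangle boundary matrix over GF(2) and read off dim-1 pairs."""
    n = M.shape[0]
    # edge position in filtration order; bit k of a column = edge with order-index k
    edge_pos = {}
    edge_val = np.empty(len(edges))
    for pos, (w, i, j) in enumerate(edges):
        edge_pos[(i, j)] = pos
        edge_val[pos] = w

    tris = []
    for i, j, k in combinations(range(n), 3):
        w = max(M[i, j], M[i, k], M[j, k])
        tris.append((w, i, j, k))
    # triangles in filtration order; tie-break on vertex triple for determinism
    tris.sort(key=lambda t: (t[0], t[1:]))

    pivot_col: dict[int, int] = {}
    pivot_val: dict[int, float] = {}
    bars = []
    for w, i, j, k in tris:
        col = (
            (1 << edge_pos[(i, j)])
            | (1 << edge_pos[(i, k)])
            | (1 << edge_pos[(j, k)])
        )
        while col:
            low = col.bit_length() - 1
            if low not in pivot_col:
                break
            col ^= pivot_col[low]
        if col:
            low = col.bit_length() - 1
            pivot_col[low] = col
            pivot_val[low] = w
            birth = edge_val[low]
            if w > birth or keep_zero_bars:
                bars.append(PersistenceBar(1, float(birth), float(w)))
    return bars


def betti_curve(bars: list[PersistenceBar], dim: int, grid) -> BettiCurve:
    """Count bars alive on the half-open interval [birth, death) at each grid point."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or (grid.size > 1 and np.any(np.diff(grid) < 0)):
        raise ValueError("grid must be one-dimensional and ascending")
    counts = np.zeros(grid.size, dtype=int)
    for b in bars:
        if b.dim != dim:
            continue
        counts += (grid >= b.birth) & (grid < b.death)
    return BettiCurve(grid=grid, counts=counts, dim=dim)


def default_grid(n_points: int = 512, upper: float = 1.0) -> np.ndarray:
    """Evenly spaced filtration grid on [0, upper] (matrices M are normalized to [0, 1))."""
    return np.linspace(0.0, upper, n_points)


def connected_components_at(M, rho: float) -> int:
    """Number of connected components of the graph with edges M_ij <= rho.

    Equals beta_0(rho) of the Rips filtration under the [birth, death)
    convention at any rho that is not itself a death value; at a death value
    the merge has already happened (edges enter at rho inclusive).
    """
    M = _validated(M)
    n = M.shape[0]
    adj = (M <= rho).astype(np.int8)
    np.fill_diagonal(adj, 0)
    n_comp, _ = _cc(sp.csr_matrix(adj), directed=False)
    return int(n_comp)
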