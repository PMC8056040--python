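"""Bipartite species x community network specialization.

The interaction matrix counts stems of each species in each community.  The
network-level specialization index H2' rescales the Shannon entropy of the
interaction proportions between its extremes under fixed marginal totals:

    H2  = -sum_ij p_ij ln p_ij,            p_ij = a_ij / m
    H2' = (H2max - H2) / (H2max - H2min)

H2' = 0 means interactions follow the marginal totals (no specialization);
H2' = 1 means maximal specialization given the marginals.  Connectance is
the fraction of realized species-community links.

H2max is the entropy of the continuous independence distribution
``r_i c_j / m^2`` (the sum of the two marginal entropies).  H2min comes from
a greedy integer allocation that concentrates interactions as far as the
marginals allow; an exact integer-constrained H2max search is available
behind a flag for sensitivity analysis.  Natural logarithms throughout.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .census import QuadratMatrix

__all__ = [
    "BipartiteNetwork",
    "build_network",
    "h2_entropy",
    "h2_bounds",
    "h2prime",
    "connectance",
]


@dataclass
class BipartiteNetwork:
    """Species x community abundance totals with entropy-based indices."""

    matrix: pd.DataFrame  # species rows, community columns, integer counts

    def __post_init__(self) -> None:
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("interaction counts must be nonnegative")

    @property
    def m(self) -> int:
        return int(self.matrix.to_numpy().sum())

    def edge_list(self) -> pd.DataFrame:
        long = self.matrix.stack()
        long = long[long > 0]
        out = long.reset_index()
        out.columns = ["species", "community", "weight"]
        return out


def build_network(qm: QuadratMatrix) -> BipartiteNetwork:
    """Collapse a quadrat matrix to species x community totals."""
    totals = qm.community_totals()
    totals = totals.loc[totals.sum(axis=1) > 0]
    return BipartiteNetwork(matrix=totals.astype(int))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def h2_entropy(net: BipartiteNetwork) -> float:
    """Shannon entropy H2 of the interaction proportions (natural log)."""
    m = net.m
    if m == 0:
        raise ValueError("empty interaction matrix")
    return _entropy(net.matrix.to_numpy(dtype=float).ravel() / m)


def _greedy_min_entropy(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Concentrated integer allocation with the given marginals.

    Repeatedly place ``min(remaining row, remaining column)`` into the cell
    whose remaining row x column product is currently largest.  This packs
    interactions into as few cells as the marginals permit, approximating
    the minimum-entropy table.
    """
    r = rows.astype(np.int64).copy()
    c = cols.astype(np.int64).copy()
    A = np.zeros((len(r), len(c)), dtype=np.int64)
    # max-heap on remaining products, lazily re-validated
    heap = [(-int(ri) * int(cj), i, j) for i, ri in enumerate(r) for j, cj in enumerate(c)]
    heapq.heapify(heap)
    while heap:
        negp, i, j = heapq.heappop(heap)
        cur = int(r[i]) * int(c[j])
        if cur == 0:
            continue
        if -negp != cur:  # stale entry: reinsert with the current product
            heapq.heappush(heap, (-cur, i, j))
            continue
        put = min(r[i], c[j])
        A[i, j] += put
        r[i] -= put
        c[j] -= put
    return A


def _exhaustive_min_entropy(rows: np.ndarray, cols: np.ndarray) -> float:
    """Exact minimum entropy over integer tables with the given marginals.

    Exponential enumeration; used only for small grand totals where the
    greedy allocation's known heuristic gap would matter.
    """
    m = rows.sum()
    best = [np.inf]

    def rec(i: int, cols_left: np.ndarray, filled: list[np.ndarray]) -> None:
        if i == len(rows):
            A = np.array(filled, dtype=float)
            best[0] = min(best[0], _entropy(A.ravel() / m))
            return
        for row in _compositions(int(rows[i]), cols_left):
            rec(i + 1, cols_left - row, filled + [row])

    rec(0, cols.astype(np.int64).copy(), [])
    return best[0]


def _exhaustive_max_entropy(rows: np.ndarray, cols: np.ndarray) -> float:
    """Exact integer-constrained maximum entropy (exponential; tiny m only)."""
    best = [-np.inf]

    def rec(i: int, cols_left: np.ndarray, filled: list[np.ndarray]) -> None:
        if i == len(rows):
            A = np.array(filled, dtype=float)
            best[0] = max(best[0], _entropy(A.ravel() / A.sum()))
            return
        for row in _compositions(int(rows[i]), cols_left):
            rec(i + 1, cols_left - row, filled + [row])

    rec(0, cols.astype(np.int64).copy(), [])
    return best[0]


def _compositions(total: int, caps: np.ndarray):
    """All nonnegative integer vectors summing to ``total`` with ``v <= caps``."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield np.array([total])
        return
    for k in range(min(total, int(caps[0])) + 1):
        for rest in _compositions(total - k, caps[1:]):
            yield np.concatenate([[k], rest])


def h2_bounds(
    net: BipartiteNetwork, *, integer_max: bool = False, exact_min_total: int = 12
) -> tuple[float, float]:
    """Entropy bounds (H2min, H2max) under the observed marginal totals.

    ``H2max`` defaults to the entropy of the independence distribution
    ``r_i c_j / m^2``, i.e. the sum of the marginal entropies; with
    ``integer_max=True`` an exact search over integer tables is used instead
    (feasible only for very small totals).

    ``H2min`` is exact (full enumeration) while the grand total is at most
    ``exact_min_total``; beyond that the greedy allocation is used, which
    can overshoot the true minimum slightly on adversarial marginals.
    """
    M = net.matrix.to_numpy(dtype=np.int64)
    m = M.sum()
    if m == 0:
        raise ValueError("empty interaction matrix")
    rows = M.sum(axis=1)
    cols = M.sum(axis=0)
    if integer_max:
        h2max = _exhaustive_max_entropy(rows, cols)
    else:
        h2max = _entropy(rows / m) + _entropy(cols / m)
    if m <= exact_min_total:
        h2min = _exhaustive_min_entropy(rows, cols)
    else:
        A = _greedy_min_entropy(rows, cols)
        h2min = _entropy(A.ravel() / m)
    return h2min, h2max


def h2prime(net: BipartiteNetwork, *, integer_max: bool = False) -> float:
    """Network specialization H2' in [0, 1].

    Degenerate case ``H2max == H2min`` (a single species or community, or
    marginals admitting exactly one table) is reported as 0.
    """
    h2min, h2max = h2_bounds(net, integer_max=integer_max)
    if h2max - h2min <= 1e-12:
        return 0.0
    h2 = h2_entropy(net)
    return float(np.clip((h2max - h2) / (h2max - h2min), 0.0, 1.0))


def connectance(net: BipartiteNetwork) -> float:
    """Realized links / possible links."""
    M = net.matrix.to_numpy()
    if M.size == 0:
        raise ValueError("empty interaction matrix")
    return float((M > 0).sum() / M.size)
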