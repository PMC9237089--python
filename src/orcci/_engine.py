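"""Index-based curvature engine shared by bulk curvature and the removal loop.

Maintains, for the evolving residual graph:

* a dense boolean adjacency matrix ``A``;
* exact walk-count matrices ``A2 = A@A`` and ``A3 = A@A2`` (int64), updated
  incrementally on edge deletion, from which hop-distance classes
  {0, 1, 2, 3, >3} are read off. These suffice because every ground distance
  entering the Wasserstein term of an existing edge is at most 3 hops.
* per-edge curvature values with an input-signature cache: an edge is re-solved
  only when its endpoint neighborhoods or their pairwise distance submatrix
  actually changed, which keeps incremental recomputation bit-identical to a
  full recomputation.

Node indices follow the lexicographic order of node ids, so index-tuple
comparisons reproduce the documented lexicographic tie-breaks.
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd

import numpy as np

from ._transport import _mcf, _transport_linprog
from .errors import GraphError
from .network import Network

__all__ = ["CurvatureEngine"]


def _lcm(a: int, b: int) -> int:
    return a * b // gcd(a, b)


class CurvatureEngine:
    """Curvature bookkeeping for one Network under one laziness setting.

    With ``frozen_distances=True`` the ground distances for every transport
    problem stay those of the graph passed at construction, while the mass
    distributions still follow the evolving residual neighborhoods; with the
    default False, distances are recomputed on the residual graph.
    """

    def __init__(self, net: Network, laziness: float = 0.0,
                 frozen_distances: bool = False):
        if not 0.0 <= laziness < 1.0:
            raise GraphError(f"laziness must be in [0, 1), got {laziness}")
        self.frozen_distances = bool(frozen_distances)
        self.node_ids: list[str] = sorted(net.nodes)
        self.index: dict[str, int] = {v: i for i, v in enumerate(self.node_ids)}
        n = len(self.node_ids)
        self.n = n
        self.laziness = float(laziness)
        frac = Fraction(self.laziness).limit_denominator(10**6)
        self._alpha: Fraction | None = (
            frac if abs(float(frac) - self.laziness) < 1e-12 else None
        )
        self.A = np.zeros((n, n), dtype=bool)
        self.edges: set[tuple[int, int]] = set()
        for u, v in net.edges:
            i, j = self.index[u], self.index[v]
            if i > j:
                i, j = j, i
            self.A[i, j] = True
            self.A[j, i] = True
            self.edges.add((i, j))
        self._neigh: list[set[int]] = [set(np.nonzero(self.A[i])[0]) for i in range(n)]
        self._neigh_arr: list[np.ndarray | None] = [None] * n
        self._recompute_reach()
        if self.frozen_distances:
            self._dA = self.A.copy()
        else:
            self._dA = self.A
        self.kappa: dict[tuple[int, int], float] = {}
        self._sig: dict[tuple[int, int], tuple[bytes, bytes, bytes]] = {}
        for e in sorted(self.edges):
            self._solve_edge(e)

    # ------------------------------------------------------------------ reach

    def _recompute_reach(self) -> None:
        """Full recomputation of walk-count matrices (exact in float64)."""
        af = self.A.astype(np.float64)
        a2 = af @ af
        a3 = af @ a2
        self.A2 = a2.astype(np.int64)
        self.A3 = a3.astype(np.int64)

    def _update_reach_on_removal(self, x: int, y: int, ax: np.ndarray, ay: np.ndarray) -> None:
        """Exact incremental update of A2, A3 after deleting edge (x, y).

        `ax`, `ay` are the pre-removal boolean adjacency rows of x and y
        (self.A has already been updated).
        """
        a2x_old = self.A2[:, x].copy()
        a2y_old = self.A2[:, y].copy()
        axi = ax.astype(np.int64)
        ayi = ay.astype(np.int64)
        # A2 += Delta@A + A@Delta + Delta@Delta
        self.A2[x, :] -= ayi
        self.A2[y, :] -= axi
        self.A2[:, x] -= ayi
        self.A2[:, y] -= axi
        self.A2[x, x] += 1
        self.A2[y, y] += 1
        # A3 += Delta@A2_new + A_old@DeltaA2
        self.A3[x, :] -= self.A2[y, :]
        self.A3[y, :] -= self.A2[x, :]
        nx_idx = np.nonzero(ax)[0]
        ny_idx = np.nonzero(ay)[0]
        self.A3[np.ix_(nx_idx, ny_idx)] -= 1
        self.A3[np.ix_(ny_idx, nx_idx)] -= 1
        self.A3[:, x] -= a2y_old
        self.A3[:, y] -= a2x_old
        self.A3[:, x] += axi
        self.A3[:, y] += ayi

    def ball3(self, x: int, y: int) -> np.ndarray:
        """Boolean mask of nodes within hop distance 3 of x or y, measured on
        the distance-reference graph (the residual graph, or the construction
        graph when distances are frozen — a superset of the residual ball)."""
        mask = (
            self._dA[x] | self._dA[y]
            | (self.A2[x] > 0) | (self.A2[y] > 0)
            | (self.A3[x] > 0) | (self.A3[y] > 0)
        )
        mask[x] = True
        mask[y] = True
        return mask

    # ------------------------------------------------------------- curvature

    def _nbr(self, i: int) -> np.ndarray:
        arr = self._neigh_arr[i]
        if arr is None:
            arr = np.fromiter(sorted(self._neigh[i]), dtype=np.int64,
                              count=len(self._neigh[i]))
            self._neigh_arr[i] = arr
        return arr

    def _cost_submatrix(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        sub = np.full((rows.size, cols.size), 4, dtype=np.int64)
        ix = np.ix_(rows, cols)
        sub[self.A3[ix] > 0] = 3
        sub[self.A2[ix] > 0] = 2
        sub[self._dA[ix]] = 1
        sub[rows[:, None] == cols[None, :]] = 0
        return sub

    def _solve_edge(self, e: tuple[int, int]) -> float:
        x, y = e
        nx_arr = self._nbr(x)
        ny_arr = self._nbr(y)
        dx, dy = nx_arr.size, ny_arr.size
        alpha = self._alpha
        if self.laziness == 0.0:
            rows, cols = nx_arr, ny_arr
        else:
            rows = np.concatenate(([x], nx_arr))
            cols = np.concatenate(([y], ny_arr))
        cost = self._cost_submatrix(rows, cols)
        if np.any(cost >= 4):  # pragma: no cover - impossible while (x, y) exists
            raise GraphError(f"support pair beyond 3 hops for edge {e}")
        sig = (nx_arr.tobytes(), ny_arr.tobytes(), cost.tobytes())
        old = self._sig.get(e)
        if old == sig:
            return self.kappa[e]
        if alpha is not None:
            if self.laziness == 0.0:
                scale = _lcm(dx, dy)
                sup = np.full(dx, scale // dx, dtype=np.int64)
                dem = np.full(dy, scale // dy, dtype=np.int64)
            else:
                p, q = alpha.numerator, alpha.denominator
                ell = _lcm(dx, dy)
                scale = q * ell
                sup = np.empty(dx + 1, dtype=np.int64)
                sup[0] = p * ell
                sup[1:] = (q - p) * ell // dx
                dem = np.empty(dy + 1, dtype=np.int64)
                dem[0] = p * ell
                dem[1:] = (q - p) * ell // dy
            total = _mcf(sup, dem, cost)
            w = float(total) / float(scale)
        else:
            mu = np.full(dx, (1.0 - self.laziness) / dx)
            nu = np.full(dy, (1.0 - self.laziness) / dy)
            if self.laziness != 0.0:
                mu = np.concatenate(([self.laziness], mu))
                nu = np.concatenate(([self.laziness], nu))
            w = _transport_linprog(mu, nu, cost.astype(float))
        kappa = 1.0 - w
        self.kappa[e] = kappa
        self._sig[e] = sig
        return kappa

    # ------------------------------------------------------------- mutation

    def remove_edge(self, e: tuple[int, int], full_recompute: bool = False) -> list[tuple[int, int]]:
        """Delete edge `e`, refresh curvature, return the recomputed edge set.

        With ``full_recompute`` every surviving edge is re-solved from scratch
        (reach matrices included); otherwise only edges with an endpoint within
        3 hops (pre-removal) of the deleted edge are revisited, and of those
        only the ones whose transport inputs changed are re-solved.
        """
        x, y = e
        if e not in self.edges:
            raise GraphError(f"edge {e} not present")
        ball = self.ball3(x, y)  # pre-removal
        ax = self.A[x].copy()
        ay = self.A[y].copy()
        self.A[x, y] = False
        self.A[y, x] = False
        self.edges.remove(e)
        self._neigh[x].remove(y)
        self._neigh[y].remove(x)
        self._neigh_arr[x] = None
        self._neigh_arr[y] = None
        del self.kappa[e]
        del self._sig[e]
        if full_recompute:
            if not self.frozen_distances:
                self._recompute_reach()
            touched = sorted(self.edges)
            self._sig.clear()
        elif self.frozen_distances:
            # Distances cannot change, so only edges losing a support node
            # (those incident to x or y) can change curvature.
            touched = sorted(
                (a, b) for (a, b) in self.edges
                if a == x or a == y or b == x or b == y
            )
        else:
            self._update_reach_on_removal(x, y, ax, ay)
            touched = sorted(
                (a, b) for (a, b) in self.edges if ball[a] or ball[b]
            )
        for edge in touched:
            self._solve_edge(edge)
        return touched

    # ------------------------------------------------------------- reporting

    def edge_ids(self, e: tuple[int, int]) -> tuple[str, str]:
        return (self.node_ids[e[0]], self.node_ids[e[1]])

    def curvature_by_ids(self) -> dict[tuple[str, str], float]:
        return {self.edge_ids(e): k for e, k in self.kappa.items()}
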