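"""Exact Wasserstein-1 transport kernels.

Two interchangeable backends solve the discrete transportation problem
(minimize sum f_ij * c_ij subject to row sums = mu, column sums = nu, f >= 0):

* ``flow`` — successive-shortest-path min-cost flow on integer-scaled masses
  (numba-jitted, exact integer arithmetic). Used whenever the masses admit an
  exact small-denominator rational representation, which covers the neighbor
  mass distributions arising from unweighted graphs.
* ``linprog`` — scipy HiGHS on the float LP; the general fallback and the
  verification backend.

Both are deterministic; the flow backend breaks Dijkstra ties by node index.
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd, isinf

import numpy as np
from numba import njit

from .errors import TransportUndefinedError

__all__ = ["transport_cost", "rationalize_masses"]

_INF = np.int64(2**62)

# Largest common denominator accepted for the integer backend. Masses from
# unweighted-graph neighborhoods have denominators lcm(q, deg_x, deg_y) with
# q the laziness denominator, comfortably below this.
_MAX_DENOM = 10**12


@njit(cache=False)
def _mcf(sup, dem, cost):  # pragma: no cover - exercised via transport_cost
    """Min-cost transportation by successive shortest paths with potentials.

    sup, dem: int64 supplies/demands (equal totals); cost: int64 matrix.
    Returns total cost (int64), or -1 if some demand is unreachable.
    """
    m = sup.shape[0]
    n = dem.shape[0]
    flow = np.zeros((m, n), dtype=np.int64)
    rem_s = sup.copy()
    rem_d = dem.copy()
    pot_u = np.zeros(m, dtype=np.int64)
    pot_v = np.zeros(n, dtype=np.int64)
    remaining = np.int64(0)
    for j in range(n):
        remaining += rem_d[j]

    while remaining > 0:
        dist_r = np.full(m, _INF, dtype=np.int64)
        dist_c = np.full(n, _INF, dtype=np.int64)
        done_r = np.zeros(m, dtype=np.bool_)
        done_c = np.zeros(n, dtype=np.bool_)
        prev_c = np.full(n, -1, dtype=np.int64)  # column's predecessor row
        prev_r = np.full(m, -1, dtype=np.int64)  # row's predecessor column
        for i in range(m):
            if rem_s[i] > 0:
                dist_r[i] = 0
        # Dijkstra over the bipartite residual graph (O((m+n)^2) scan).
        while True:
            best = _INF
            kind = -1
            idx = -1
            for i in range(m):
                if not done_r[i] and dist_r[i] < best:
                    best = dist_r[i]
                    kind = 0
                    idx = i
            for j in range(n):
                if not done_c[j] and dist_c[j] < best:
                    best = dist_c[j]
                    kind = 1
                    idx = j
            if kind < 0:
                break
            if kind == 0:
                i = idx
                done_r[i] = True
                for j in range(n):
                    if not done_c[j]:
                        nd = dist_r[i] + cost[i, j] + pot_u[i] - pot_v[j]
                        if nd < dist_c[j]:
                            dist_c[j] = nd
                            prev_c[j] = i
            else:
                j = idx
                done_c[j] = True
                for i in range(m):
                    if not done_r[i] and flow[i, j] > 0:
                        nd = dist_c[j] - cost[i, j] - pot_u[i] + pot_v[j]
                        if nd < dist_r[i]:
                            dist_r[i] = nd
                            prev_r[i] = j
        # Closest column still in deficit (ties -> smallest index).
        t = -1
        best = _INF
        for j in range(n):
            if rem_d[j] > 0 and dist_c[j] < best:
                best = dist_c[j]
                t = j
        if t < 0:
            return np.int64(-1)
        # Update potentials (Johnson), capped at the target distance.
        for i in range(m):
            d = dist_r[i] if dist_r[i] < best else best
            pot_u[i] += d
        for j in range(n):
            d = dist_c[j] if dist_c[j] < best else best
            pot_v[j] += d
        # Trace the augmenting path and find its bottleneck.
        amount = rem_d[t]
        j = t
        while True:
            i = prev_c[j]
            if rem_s[i] > 0 and prev_r[i] < 0:
                if rem_s[i] < amount:
                    amount = rem_s[i]
                break
            jj = prev_r[i]
            if flow[i, jj] < amount:
                amount = flow[i, jj]
            j = jj
        # Apply the augmentation.
        j = t
        while True:
            i = prev_c[j]
            flow[i, j] += amount
            if rem_s[i] > 0 and prev_r[i] < 0:
                rem_s[i] -= amount
                break
            jj = prev_r[i]
            flow[i, jj] -= amount
            j = jj
        rem_d[t] -= amount
        remaining -= amount

    total = np.int64(0)
    for i in range(m):
        for j in range(n):
            if flow[i, j] > 0:
                total += flow[i, j] * cost[i, j]
    return total


def rationalize_masses(mass: np.ndarray, tol: float = 1e-12):
    """Exact small-denominator rational form of a probability vector.

    Returns (numerators, common_denominator) with numerators/denominator
    reproducing every entry to within `tol` and summing exactly to the
    denominator, or None when no such representation exists.
    """
    fracs = []
    for x in mass:
        f = Fraction(float(x)).limit_denominator(10**9)
        if abs(float(f) - float(x)) > tol:
            return None
        fracs.append(f)
    if sum(fracs) != 1:
        return None
    denom = 1
    for f in fracs:
        denom = denom * f.denominator // gcd(denom, f.denominator)
        if denom > _MAX_DENOM:
            return None
    nums = np.array([int(f * denom) for f in fracs], dtype=np.int64)
    return nums, denom


def _transport_linprog(mu: np.ndarray, nu: np.ndarray, cost: np.ndarray) -> float:
    import scipy.sparse as sp
    from scipy.optimize import linprog

    m, n = cost.shape
    rows = sp.kron(sp.eye(m), np.ones((1, n)))
    cols = sp.kron(np.ones((1, m)), sp.eye(n))
    a_eq = sp.vstack([rows, cols]).tocsc()
    b_eq = np.concatenate([mu, nu])
    res = linprog(cost.ravel().astype(float), A_eq=a_eq, b_eq=b_eq,
                  bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - defensive
        raise TransportUndefinedError(f"transport LP failed: {res.message}")
    return float(res.fun)


def transport_cost(
    mu: np.ndarray, nu: np.ndarray, cost: np.ndarray, method: str = "auto"
) -> float:
    """Minimum transport cost between mass vectors `mu` and `nu`.

    `cost` is a (len(mu), len(nu)) matrix of finite non-negative ground
    distances. `method` is ``auto`` (integer flow when masses are exactly
    rational, else LP), ``flow`` or ``linprog``.
    """
    mu = np.asarray(mu, dtype=float)
    nu = np.asarray(nu, dtype=float)
    cost = np.asarray(cost)
    if cost.shape != (mu.size, nu.size):
        raise ValueError(f"cost shape {cost.shape} != ({mu.size}, {nu.size})")
    if np.any(~np.isfinite(cost.astype(float))):
        raise TransportUndefinedError(
            "infinite ground distance: supports lie in different components"
        )
    if method not in ("auto", "flow", "linprog"):
        raise ValueError(f"unknown transport method {method!r}")

    if method in ("auto", "flow"):
        ra = rationalize_masses(mu)
        rb = rationalize_masses(nu)
        cost_int = np.asarray(np.round(cost), dtype=np.int64)
        integral_cost = bool(np.all(np.abs(cost.astype(float) - cost_int) < 1e-12))
        if ra is not None and rb is not None and integral_cost:
            na, da = ra
            nb, db = rb
            lcm = da * db // gcd(da, db)
            sup = na * (lcm // da)
            dem = nb * (lcm // db)
            total = _mcf(sup, dem, cost_int)
            if total < 0:  # pragma: no cover - guarded by the finite check
                raise TransportUndefinedError("transport infeasible")
            return float(total) / float(lcm)
        if method == "flow":
            raise ValueError(
                "flow backend requires exactly-rational masses and integer costs"
            )
    return _transport_linprog(mu, nu, cost.astype(float))
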