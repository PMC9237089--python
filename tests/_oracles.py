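"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package's solvers: exact Fraction
arithmetic and exhaustive search over vertex solutions of the transportation
polytope.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache

import networkx as nx


def transport_cost_oracle(mu, nu, cost) -> Fraction:
    """Exact minimum transport cost by exhaustive saturating-move search.

    Every vertex of the transportation polytope has forest support and is
    reachable by a sequence of moves that each ship min(remaining row,
    remaining column) mass along one cell, saturating a row or a column; the
    memoized recursion below therefore visits an optimal vertex. Masses are
    Fractions, so the result is exact.
    """
    mu = tuple(Fraction(x) for x in mu)
    nu = tuple(Fraction(x) for x in nu)
    cost = tuple(tuple(Fraction(c) for c in row) for row in cost)
    assert sum(mu) == sum(nu)

    @lru_cache(maxsize=None)
    def best(rem_a: tuple, rem_b: tuple) -> Fraction:
        if all(a == 0 for a in rem_a):
            return Fraction(0)
        out = None
        for i, a in enumerate(rem_a):
            if a == 0:
                continue
            for j, b in enumerate(rem_b):
                if b == 0:
                    continue
                ship = min(a, b)
                na = list(rem_a)
                nb = list(rem_b)
                na[i] -= ship
                nb[j] -= ship
                sub = ship * cost[i][j] + best(tuple(na), tuple(nb))
                if out is None or sub < out:
                    out = sub
        return out

    return best(mu, nu)


def edge_orc_oracle(g: nx.Graph, u, v) -> Fraction:
    """Curvature of edge (u, v) of `g` from the enumeration oracle.

    Uniform neighbor masses, hop-distance ground costs on `g`, exact
    Fractions throughout.
    """
    nu_nodes = sorted(g.neighbors(u))
    nv_nodes = sorted(g.neighbors(v))
    mu = [Fraction(1, len(nu_nodes))] * len(nu_nodes)
    nv = [Fraction(1, len(nv_nodes))] * len(nv_nodes)
    dist = dict(nx.single_source_shortest_path_length(g, u))
    cost = []
    for a in nu_nodes:
        da = dict(nx.single_source_shortest_path_length(g, a))
        cost.append([Fraction(da[b]) for b in nv_nodes])
    w = transport_cost_oracle(mu, nv, cost)
    return 1 - w


def connected_atlas(max_nodes: int = 6) -> list[nx.Graph]:
    """All connected graphs with 1..max_nodes nodes (from the graph atlas)."""
    out = []
    for g in nx.graph_atlas_g()[1:]:
        if g.number_of_nodes() > max_nodes:
            break
        if g.number_of_nodes() >= 1 and nx.is_connected(g):
            out.append(g)
    return out
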