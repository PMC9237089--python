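"""Ollivier-Ricci curvature of graph edges.

For an edge (x, y) of an unweighted graph, the curvature is

    kappa(x, y) = 1 - W1(m_x, m_y) / d(x, y),

where m_x spreads probability mass uniformly over the neighbors of x (a
`laziness` fraction may optionally stay on x itself), W1 is the Wasserstein-1
(earth mover's) distance under hop-distance ground costs, and d(x, y) = 1 for
an existing edge. Positive curvature marks edges inside densely interconnected
neighborhoods; negative curvature marks bridges between them.

Ground distances are always measured on the *current* graph, so curvature
tracks the evolving topology as edges are removed.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._engine import CurvatureEngine
from ._transport import transport_cost
from .errors import GraphError, TransportUndefinedError, UndefinedDistributionError
from .network import Edge, Network, normalize_edge

__all__ = [
    "CurvatureConfig",
    "MassDistribution",
    "neighbor_mass",
    "wasserstein1",
    "edge_orc",
    "all_edge_orc",
    "affected_edges",
]

#: Any shortest path between support nodes of an existing edge has length <= 3
#: (neighbor, endpoint, endpoint, neighbor), so a deleted edge farther away
#: cannot change another edge's curvature.
AFFECTED_RADIUS = 3


@dataclass(frozen=True)
class CurvatureConfig:
    """Curvature parameters.

    laziness
        Fraction of mass retained at the center node, in [0, 1). The default 0
        spreads all mass uniformly over the neighbors.
    tolerance
        Feasibility/verification tolerance for the transport solve.
    method
        Transport backend: ``auto`` (exact integer flow when possible, LP
        otherwise), ``flow`` or ``linprog``.
    """

    laziness: float = 0.0
    tolerance: float = 1e-9
    method: str = "auto"

    def __post_init__(self) -> None:
        if not 0.0 <= self.laziness < 1.0:
            raise GraphError(f"laziness must be in [0, 1), got {self.laziness}")


@dataclass(frozen=True)
class MassDistribution:
    """A probability distribution over a small set of distinct nodes."""

    support: tuple[str, ...]
    mass: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.support) != len(self.mass):
            raise GraphError("support and mass lengths differ")
        if len(set(self.support)) != len(self.support):
            raise GraphError("support nodes must be distinct")
        if any(m < 0 for m in self.mass):
            raise GraphError("negative mass")
        if abs(sum(self.mass) - 1.0) > 1e-9:
            raise GraphError(f"mass sums to {sum(self.mass)}, not 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.support, self.mass))


def neighbor_mass(net: Network, x: str, cfg: CurvatureConfig | None = None) -> MassDistribution:
    """Mass distribution m_x: `laziness` at x, the rest uniform on its neighbors."""
    cfg = cfg or CurvatureConfig()
    nbrs = sorted(net.neighbors(x))
    if not nbrs:
        raise UndefinedDistributionError(
            f"node {x!r} is isolated; its neighbor mass distribution is undefined"
        )
    share = (1.0 - cfg.laziness) / len(nbrs)
    if cfg.laziness == 0.0:
        return MassDistribution(tuple(nbrs), tuple(share for _ in nbrs))
    return MassDistribution(
        (x, *nbrs), (cfg.laziness, *(share for _ in nbrs))
    )


def wasserstein1(
    mu: MassDistribution,
    nu: MassDistribution,
    dist: Mapping[tuple[str, str], float] | np.ndarray,
    method: str = "auto",
) -> float:
    """Wasserstein-1 distance between `mu` and `nu` under ground distances `dist`.

    `dist` is either a (len(mu), len(nu)) array aligned with the supports or a
    mapping keyed by (mu-support node, nu-support node). Infinite entries
    (supports in different components) raise TransportUndefinedError.
    """
    if isinstance(dist, Mapping):
        table = np.array(
            [[dist[(u, v)] for v in nu.support] for u in mu.support], dtype=float
        )
    else:
        table = np.asarray(dist, dtype=float)
    if np.any(table < 0):
        raise TransportUndefinedError("negative ground distance")
    return transport_cost(np.array(mu.mass), np.array(nu.mass), table, method=method)


def _support_distances(
    net: Network, mu: MassDistribution, nu: MassDistribution
) -> np.ndarray:
    g = net.to_networkx()
    table = np.full((len(mu.support), len(nu.support)), np.inf)
    targets = {v: j for j, v in enumerate(nu.support)}
    for i, u in enumerate(mu.support):
        lengths = nx.single_source_shortest_path_length(g, u, cutoff=AFFECTED_RADIUS)
        for v, j in targets.items():
            if v in lengths:
                table[i, j] = lengths[v]
    return table


def edge_orc(net: Network, e: tuple[str, str], cfg: CurvatureConfig | None = None) -> float:
    """Ollivier-Ricci curvature of a single edge (reference implementation).

    Hop distances are taken on `net` itself (the current residual graph when
    called from the removal loop).
    """
    cfg = cfg or CurvatureConfig()
    u, v = normalize_edge(*e)
    if not net.has_edge(u, v):
        raise GraphError(f"edge {(u, v)!r} not in network")
    mu = neighbor_mass(net, u, cfg)
    nu = neighbor_mass(net, v, cfg)
    table = _support_distances(net, mu, nu)
    w = wasserstein1(mu, nu, table, method=cfg.method)
    return 1.0 - w


def all_edge_orc(net: Network, cfg: CurvatureConfig | None = None) -> dict[Edge, float]:
    """Curvature of every edge of `net`, keyed by normalized edge."""
    cfg = cfg or CurvatureConfig()
    if net.n_edges == 0:
        return {}
    if cfg.method == "linprog":
        return {e: edge_orc(net, e, cfg) for e in sorted(net.edges)}
    engine = CurvatureEngine(net, laziness=cfg.laziness)
    return engine.curvature_by_ids()


def affected_edges(net: Network, removed: tuple[str, str]) -> set[Edge]:
    """Edges whose curvature may change when `removed` is deleted from `net`.

    `net` is the pre-removal graph. Returns every other edge with an endpoint
    within AFFECTED_RADIUS hops of an endpoint of `removed`; recomputing
    exactly these edges reproduces a full recomputation.
    """
    u, v = normalize_edge(*removed)
    if not net.has_edge(u, v):
        raise GraphError(f"edge {(u, v)!r} not in network")
    g = net.to_networkx()
    ball: set[str] = set()
    for s in (u, v):
        ball.update(nx.single_source_shortest_path_length(g, s, cutoff=AFFECTED_RADIUS))
    e0 = normalize_edge(u, v)
    return {e for e in net.edges if e != e0 and (e[0] in ball or e[1] in ball)}
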