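"""Core data model: undirected unweighted graphs, node labels, partitions.

Node ids are opaque strings (locus tags like ``AT1G22920`` survive untouched);
edges are stored in a normalized orientation with endpoints in lexicographic
order, so ``(u, v)`` and ``(v, u)`` denote the same edge.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from functools import cached_property
from typing import Hashable

import networkx as nx

from .errors import GraphError

__all__ = ["Network", "SideInfo", "Partition", "normalize_edge"]

Edge = tuple[str, str]


def normalize_edge(u: str, v: str) -> Edge:
    """Return the canonical orientation of an undirected edge (lexicographic)."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Network:
    """An undirected, unweighted simple graph.

    Parameters
    ----------
    nodes
        All node ids, including isolated (degree-0) nodes.
    edges
        Normalized unordered pairs; every endpoint must appear in `nodes`.
    """

    nodes: frozenset[str]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise GraphError(f"self-loop on node {u!r}")
            if u > v:
                raise GraphError(f"edge {(u, v)!r} not in normalized orientation")
            if u not in self.nodes or v not in self.nodes:
                raise GraphError(f"edge {(u, v)!r} has an endpoint outside the node set")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "Network":
        """Build a Network, normalizing edge orientation and collapsing duplicates.

        Self-loops raise; pass extra `nodes` to retain isolated nodes.
        """
        norm = frozenset(normalize_edge(str(u), str(v)) for u, v in edges)
        all_nodes = frozenset(str(n) for n in nodes) | frozenset(
            x for e in norm for x in e
        )
        return cls(nodes=all_nodes, edges=norm)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @cached_property
    def _adjacency(self) -> dict[str, frozenset[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return {n: frozenset(s) for n, s in adj.items()}

    def neighbors(self, node: str) -> frozenset[str]:
        try:
            return self._adjacency[node]
        except KeyError:
            raise GraphError(f"node {node!r} not in network") from None

    def degree(self, node: str) -> int:
        return len(self.neighbors(node))

    def has_edge(self, u: str, v: str) -> bool:
        return normalize_edge(u, v) in self.edges

    def remove_edge(self, u: str, v: str) -> "Network":
        e = normalize_edge(u, v)
        if e not in self.edges:
            raise GraphError(f"edge {e!r} not in network")
        return Network(nodes=self.nodes, edges=self.edges - {e})

    def subgraph(self, keep: Iterable[str]) -> "Network":
        """Induced subgraph: retained edges have both endpoints in `keep`."""
        keep_set = frozenset(keep)
        missing = keep_set - self.nodes
        if missing:
            raise GraphError(f"nodes not in network: {sorted(missing)[:5]}")
        return Network(
            nodes=keep_set,
            edges=frozenset(e for e in self.edges if e[0] in keep_set and e[1] in keep_set),
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        return cls.from_edges(g.edges(), nodes=g.nodes())


@dataclass(frozen=True)
class SideInfo:
    """A-priori node labels: node id -> non-empty set of community/function labels.

    Association with a particular Network is checked at use time, not here;
    labeled nodes absent from a graph are simply inert.
    """

    labels: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node, labs in self.labels.items():
            if not labs:
                raise GraphError(f"empty label set for node {node!r}")

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[Hashable]]) -> "SideInfo":
        return cls(labels={str(n): frozenset(str(x) for x in labs) for n, labs in d.items()})

    def get(self, node: str) -> frozenset[str]:
        """Labels of `node`; empty frozenset when the node is unlabeled."""
        return self.labels.get(node, frozenset())

    def __contains__(self, node: str) -> bool:
        return node in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    def __bool__(self) -> bool:
        return bool(self.labels)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.labels)


@dataclass(frozen=True)
class Partition:
    """A total assignment node id -> community id.

    Community ids are opaque (strings or ints); communities are the preimage
    classes of the assignment.
    """

    assignment: Mapping[str, Hashable]

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.assignment)

    def __getitem__(self, node: str) -> Hashable:
        return self.assignment[node]

    def __len__(self) -> int:
        return len(self.assignment)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return dict(self.assignment) == dict(other.assignment)

    def __hash__(self) -> int:  # pragma: no cover - rarely needed
        return hash(frozenset(self.assignment.items()))

    @cached_property
    def communities(self) -> dict[Hashable, frozenset[str]]:
        """Community id -> member node set."""
        out: dict[Hashable, set[str]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, set()).add(node)
        return {cid: frozenset(m) for cid, m in out.items()}

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def sizes(self) -> list[int]:
        return sorted(len(m) for m in self.communities.values())

    def restrict(self, keep: Iterable[str]) -> "Partition":
        keep_set = frozenset(keep)
        return Partition({n: c for n, c in self.assignment.items() if n in keep_set})

    def refines(self, other: "Partition") -> bool:
        """True iff every community of self lies inside one community of `other`."""
        if self.universe != other.universe:
            return False
        for members in self.communities.values():
            images = {other[n] for n in members}
            if len(images) > 1:
                return False
        return True
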