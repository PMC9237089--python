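"""Readers and writers for the package's plain-text formats.

Canonical formats are small TSV/whitespace tables: two-column edge lists
("#" comments, optional isolated-node declarations as single-field lines),
two-column side-information files (node, label; repeated nodes accumulate a
label set), and two-column partition files (node, community id). GraphML is
supported read-only for interoperability. Graphs are strictly undirected and
unweighted; a third (weight) column is ignored with a warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx

from .errors import ParseError
from .network import Network, Partition, SideInfo, normalize_edge

__all__ = [
    "read_edge_list",
    "read_side_info",
    "read_partition",
    "write_partition",
    "write_curvature",
    "read_graphml",
]

log = logging.getLogger("orcci")


def read_edge_list(path: str | Path, delimiter: str | None = None) -> Network:
    """Parse an edge-list file into a Network.

    `delimiter=None` splits on any whitespace. Lines starting with "#" are
    comments; a single-field line declares an isolated node; duplicate and
    reversed-duplicate edges collapse; self-loops are dropped with a warning.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    nodes: list[str] = []
    n_self = 0
    warned_extra = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            # with an explicit delimiter, leading/trailing separators denote
            # empty fields and must not be stripped away
            fields = line.split() if delimiter is None else raw.rstrip("\r\n").split(delimiter)
            if any(f == "" for f in fields):
                raise ParseError(f"{path}:{lineno}: empty field")
            if len(fields) == 1:
                nodes.append(fields[0])
                continue
            if len(fields) > 2 and not warned_extra:
                log.warning(
                    "%s:%d: extra columns (e.g. weights) ignored; graphs are unweighted",
                    path,
                    lineno,
                )
                warned_extra = True
            u, v = fields[0], fields[1]
            if u == v:
                n_self += 1
                log.warning("%s:%d: self-loop on %r dropped", path, lineno, u)
                nodes.append(u)
                continue
            edges.append((u, v))
    return Network.from_edges(edges, nodes=nodes)


def read_side_info(path: str | Path, delimiter: str = "\t") -> SideInfo:
    """Parse a two-column (node, label) file; repeated nodes accumulate labels."""
    path = Path(path)
    labels: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            node, label = fields[0].strip(), fields[1].strip()
            if not node or not label:
                raise ParseError(f"{path}:{lineno}: empty node or label field")
            labels.setdefault(node, set()).add(label)
    return SideInfo({n: frozenset(s) for n, s in labels.items()})


def read_partition(path: str | Path, delimiter: str = "\t") -> Partition:
    path = Path(path)
    assignment: dict[str, str] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(f"{path}:{lineno}: expected node and community id")
            assignment[fields[0].strip()] = fields[1].strip()
    return Partition(assignment)


def write_partition(partition: Partition, path: str | Path) -> None:
    """Write (node, community id) rows sorted by node id; an empty partition
    produces an empty file. Round-trips through read_partition."""
    path = Path(path)
    with path.open("w") as fh:
        for node in sorted(partition.universe):
            fh.write(f"{node}\t{partition[node]}\n")


def write_curvature(curv: dict[tuple[str, str], float], path: str | Path) -> None:
    """Write (node_u, node_v, kappa) rows, fixed 10-decimal formatting, sorted
    by normalized edge for reproducible diffs."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in sorted(curv):
            fh.write(f"{u}\t{v}\t{curv[(u, v)]:.10f}\n")


def read_graphml(path: str | Path) -> Network:
    """Read a GraphML file (undirected view; attributes and weights ignored)."""
    g = nx.read_graphml(Path(path))
    if g.is_directed():
        log.warning("%s: directed GraphML read as undirected", path)
        g = g.to_undirected()
    edges = [(str(u), str(v)) for u, v in g.edges() if str(u) != str(v)]
    return Network.from_edges(edges, nodes=(str(n) for n in g.nodes()))
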