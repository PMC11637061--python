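"""Graph data model and file I/O.

Graphs are plain :class:`networkx.Graph` instances: undirected, simple
(no self-loops, no multi-edges), with opaque hashable node identifiers.
Loaders normalize their input to that form and attach a
:class:`LoadReport` under ``g.graph["load_report"]``.

Node identifiers read from files are kept as strings and never coerced,
so ``"01"`` and ``"1"`` remain distinct nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Mapping

import networkx as nx

from .errors import GraphDomainError, ParseError

logger = logging.getLogger(__name__)

Node = Hashable


class _Unreachable:
    """Sentinel for 'no path exists' — never an arbitrary large number."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNREACHABLE"


UNREACHABLE = _Unreachable()


@dataclass(frozen=True)
class LoadReport:
    """What a loader saw and what it dropped while normalizing."""

    nodes: int
    edges: int
    self_loops_dropped: int
    duplicates_dropped: int

    def log(self) -> None:
        logger.info(
            "graph loaded: nodes=%d edges=%d self_loops_dropped=%d "
            "duplicates_dropped=%d",
            self.nodes,
            self.edges,
            self.self_loops_dropped,
            self.duplicates_dropped,
        )


def _normalize(
    edges: Iterable[tuple[Node, Node]], declared_nodes: Iterable[Node] = ()
) -> nx.Graph:
    """Build a simple undirected graph, counting what gets dropped."""
    g = nx.Graph()
    g.add_nodes_from(declared_nodes)
    self_loops = 0
    duplicates = 0
    for u, v in edges:
        if u == v:
            self_loops += 1
            g.add_node(u)
            continue
        if g.has_edge(u, v):
            duplicates += 1
            continue
        g.add_edge(u, v)
    report = LoadReport(
        nodes=g.number_of_nodes(),
        edges=g.number_of_edges(),
        self_loops_dropped=self_loops,
        duplicates_dropped=duplicates,
    )
    g.graph["load_report"] = report
    report.log()
    return g


def read_edge_list(path: str | Path, delimiter: str = "auto") -> nx.Graph:
    """Read a plain edge list: one edge per line, two tokens per line.

    Lines beginning with ``#`` and blank lines are skipped.  With
    ``delimiter="auto"`` a line containing a comma is split on commas,
    otherwise on whitespace.  Self-loops and duplicate edges are dropped
    (counted in the load report).  Node identifiers stay strings.

    Raises
    ------
    ParseError
        If any data line has fewer than two tokens (the message names
        the 1-based line number).
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if delimiter == "auto":
                tokens = line.split(",") if "," in line else line.split()
            else:
                tokens = line.split(delimiter)
            tokens = [t.strip() for t in tokens if t.strip()]
            if len(tokens) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected at least two tokens, "
                    f"got {len(tokens)}: {line!r}"
                )
            edges.append((tokens[0], tokens[1]))
    return _normalize(edges)


def read_gml(path: str | Path) -> nx.Graph:
    """Read a GML file as an undirected simple graph.

    Directed edges are symmetrized; self-loops and parallel edges are
    dropped with a load report.  Isolated nodes declared in the file are
    kept.
    """
    try:
        g = nx.read_gml(Path(path))
    except Exception as exc:  # networkx raises a zoo of parse errors
        raise ParseError(f"{path}: not valid GML: {exc}") from exc
    return _normalize(g.edges(), declared_nodes=g.nodes())


def write_gml(g: nx.Graph, path: str | Path) -> None:
    """Write a graph as GML (round-trips through :func:`read_gml`)."""
    nx.write_gml(g, Path(path))


def remove_node_view(g: nx.Graph, i: Node) -> nx.Graph:
    """Read-only view of ``g`` without node ``i`` and its incident edges.

    ``g`` itself is unchanged.  The view has exactly ``d(i)`` fewer
    edges than ``g``.
    """
    if i not in g:
        raise GraphDomainError(f"node {i!r} not in graph")
    return nx.restricted_view(g, [i], [])


def bfs_distances(
    g: nx.Graph,
    source: Node,
    targets: Iterable[Node] | None = None,
    cutoff: int | None = None,
) -> Mapping[Node, int | _Unreachable]:
    """Unweighted shortest-path hop counts from ``source``.

    Returns a mapping over ``targets`` (all nodes if omitted); targets
    outside ``source``'s component — or beyond ``cutoff`` hops when one
    is set — map to :data:`UNREACHABLE`.  ``distance(source, source)``
    is 0.
    """
    if source not in g:
        raise GraphDomainError(f"source {source!r} not in graph")
    lengths = nx.single_source_shortest_path_length(g, source, cutoff=cutoff)
    if targets is None:
        targets = g.nodes()
    return {t: lengths.get(t, UNREACHABLE) for t in targets}
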