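"""Classical baseline centralities: degree, K-shell, eigenvector, PageRank.

These are the standard references the KLN ranking is compared against.
networkx supplies the numerics; this module fixes the conventions
(normalization, isolated-node handling, determinism) and the common
:class:`CentralityScores` result type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .errors import ConvergenceError, GraphDomainError
from .graph import Node

__all__ = [
    "CentralityScores",
    "degree_centrality",
    "k_shell",
    "eigenvector_centrality",
    "pagerank",
]


@dataclass(frozen=True)
class CentralityScores:
    """A named score per node; K-shell additionally carries integer shells."""

    method: str
    scores: Mapping[Node, float]
    kshell: Mapping[Node, int] = field(default_factory=dict)

    def ranking(self) -> list[Node]:
        """Nodes by descending score, ties broken by ascending identifier."""
        return sorted(self.scores, key=lambda v: (-self.scores[v], v))


def degree_centrality(g: nx.Graph) -> CentralityScores:
    """Degree centrality DC(i) = d(i) / (N - 1).

    Requires N >= 2 (the normalization divides by N - 1).
    """
    n = g.number_of_nodes()
    if n < 2:
        raise GraphDomainError(
            f"degree centrality needs at least 2 nodes, got {n}"
        )
    scores = {v: d / (n - 1) for v, d in g.degree()}
    return CentralityScores("dc", scores)


def k_shell(g: nx.Graph) -> CentralityScores:
    """K-shell (k-core) decomposition.

    Peripheral layers are stripped iteratively — first all nodes of
    degree <= 1 (shell 1), then degree <= 2 (shell 2), and so on — and
    each node is tagged with the index of the deepest core it survives
    into.  Isolated nodes get shell 0.  Equals the standard core number.
    """
    shells = nx.core_number(g)
    return CentralityScores(
        "kshell", {v: float(s) for v, s in shells.items()}, kshell=dict(shells)
    )


def eigenvector_centrality(
    g: nx.Graph, tol: float = 1e-8, max_iter: int = 1000
) -> CentralityScores:
    """Eigenvector centrality by power iteration, unit Euclidean norm.

    The start vector is uniform, so the result is deterministic.
    Requires at least one edge.

    Raises
    ------
    ConvergenceError
        If power iteration does not converge within ``max_iter``.
    """
    if g.number_of_edges() < 1:
        raise GraphDomainError("eigenvector centrality needs at least 1 edge")
    try:
        scores = nx.eigenvector_centrality(g, max_iter=max_iter, tol=tol)
    except nx.PowerIterationFailedConvergence as exc:
        raise ConvergenceError(
            f"eigenvector centrality did not converge in {max_iter} "
            f"iterations (tol={tol})"
        ) from exc
    return CentralityScores("ec", dict(scores))


def pagerank(
    g: nx.Graph,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> CentralityScores:
    """PageRank with uniform teleportation on the undirected graph.

    Each edge is used in both directions; scores sum to 1; isolated
    nodes keep their teleport-only mass.  Damping defaults to the
    standard 0.85.
    """
    if not 0 < damping < 1:
        raise GraphDomainError(f"damping must lie in (0, 1), got {damping}")
    if g.number_of_nodes() == 0:
        return CentralityScores("pr", {})
    try:
        scores = nx.pagerank(g, alpha=damping, tol=tol, max_iter=max_iter)
    except nx.PowerIterationFailedConvergence as exc:
        raise ConvergenceError(
            f"pagerank did not converge in {max_iter} iterations (tol={tol})"
        ) from exc
    return CentralityScores("pr", dict(scores))
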