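"""KLN: influential-node scoring via KL divergence within the neighborhood.

The score asks: if node *i* fails, how much does information flow among
its one-hop neighbors degrade?  Concretely:

1. While *i* is intact, each neighbor *j* receives information with
   probability proportional to its degree — the *real* distribution
   ``p_i(j) = d(j) / sum_{j in Γ(i)} d(j)``.
2. With *i* removed, neighbor *n* reaches neighbor *j* only through the
   remaining graph.  The *fitting* row for *n* reweights each *j* by
   ``sqrt(λ(n,j)) · d'(j)``, where ``λ(n,j) = 1/l(n,j)`` is the path
   change factor (reciprocal post-removal hop distance; 1/2 if *n* and
   *j* are disconnected — they formerly communicated through *i* in two
   hops; 1 for the row owner itself) and ``d'(j)`` is *j*'s degree
   after the removal.
3. The information-entropy loss on row *j* is the KL divergence
   ``D'_ij = KL(P_i || q_ij)`` (base-10 logarithms); losses are summed
   with K-shell weights from the intact graph:
   ``D_i = sum_j Kshell(j) · D'_ij``.
4. Damage influence ``DE(i) = D_i + d(i)``; the final score adds the
   neighborhood's pooled damage:
   ``KLN(i) = DE(i) + sqrt(sum_{j in Γ(i)} DE(j))``.

Isolated nodes have DE = KLN = 0.  Higher KLN means more influential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .centrality import k_shell
from .errors import DegenerateDistributionError, GraphDomainError
from .graph import UNREACHABLE, Node, bfs_distances, remove_node_view

__all__ = [
    "SELF",
    "NeighborhoodProfile",
    "RealDistribution",
    "FittingDistribution",
    "ScoreTable",
    "path_change_factor",
    "real_distribution",
    "post_removal_profile",
    "fitting_distribution",
    "kl_divergence",
    "node_divergence",
    "damage_influence",
    "kln_score",
    "rank_all",
]

#: Default degree floor substituted for d'(j) = 0 (a neighbor left with no
#: edges at all) so fitting rows stay normalizable; losses become large but
#: finite, preserving the "maximal damage" reading.
DEFAULT_FLOOR = 1e-10

#: Default logarithm base for KL divergence.
DEFAULT_LOG_BASE = 10.0


class _Self:
    """Marker for the row owner's own slot: l(n, n) ≡ 1 by convention."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "SELF"


SELF = _Self()


def path_change_factor(l) -> float:
    """λ for one post-removal distance: 1/l, 1/2 if unreachable, 1 for SELF.

    Parameters
    ----------
    l
        A positive integer hop count, :data:`~klnrank.graph.UNREACHABLE`,
        or :data:`SELF`.
    """
    if l is SELF:
        return 1.0
    if l is UNREACHABLE:
        return 0.5
    if not isinstance(l, (int, np.integer)) or l <= 0:
        raise GraphDomainError(f"hop count must be a positive integer, got {l!r}")
    return 1.0 / l


@dataclass(frozen=True)
class NeighborhoodProfile:
    """Everything the fitting distribution needs about Γ(i) once i is gone.

    ``post_distance`` maps ordered pairs of *distinct* neighbors to hop
    counts in the graph without the center (or UNREACHABLE); the
    diagonal is implied by the l(n,n) ≡ 1 convention.  ``kshell`` holds
    intact-graph shells.
    """

    center: Node
    neighbors: tuple[Node, ...]  # ascending node order
    pre_degree: Mapping[Node, int]
    post_degree: Mapping[Node, int]
    kshell: Mapping[Node, int]
    post_distance: Mapping[tuple[Node, Node], object]


@dataclass(frozen=True)
class RealDistribution:
    """P_i(x): degree-proportional dissemination probabilities over Γ(i)."""

    center: Node
    neighbors: tuple[Node, ...]
    probs: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))


@dataclass(frozen=True)
class FittingDistribution:
    """Q_i(x): one row q_ij per neighbor, columns aligned with neighbors."""

    center: Node
    neighbors: tuple[Node, ...]
    rows: np.ndarray  # shape (k, k), row order == column order == neighbors

    def row(self, neighbor: Node) -> np.ndarray:
        return self.rows[self.neighbors.index(neighbor)]


@dataclass(frozen=True)
class ScoreTable:
    """Per-node KLN results and the derived ranking."""

    kl: Mapping[Node, float]  # D_i
    de: Mapping[Node, float]  # DE(i)
    kln: Mapping[Node, float]  # KLN(i)
    degree: Mapping[Node, int]
    kshell: Mapping[Node, int]
    ranking: tuple[Node, ...] = field(default=())

    def to_frame(self):
        """Ranking as a DataFrame: node, kln, de, d, kshell, rank."""
        import pandas as pd

        return pd.DataFrame(
            {
                "node": list(self.ranking),
                "kln": [self.kln[v] for v in self.ranking],
                "de": [self.de[v] for v in self.ranking],
                "d": [self.degree[v] for v in self.ranking],
                "kshell": [self.kshell[v] for v in self.ranking],
                "rank": range(1, len(self.ranking) + 1),
            }
        )


def _neighbors_sorted(g: nx.Graph, i: Node) -> tuple[Node, ...]:
    return tuple(sorted(g.neighbors(i)))


def real_distribution(g: nx.Graph, i: Node) -> RealDistribution:
    """P_i over Γ(i): p_i(j) = d(j) / Σ_{j∈Γ(i)} d(j), intact-graph degrees."""
    if i not in g:
        raise GraphDomainError(f"node {i!r} not in graph")
    nbrs = _neighbors_sorted(g, i)
    if not nbrs:
        raise GraphDomainError(
            f"node {i!r} is isolated; the real distribution is undefined"
        )
    degs = np.array([g.degree(j) for j in nbrs], dtype=float)
    return RealDistribution(i, nbrs, degs / degs.sum())


def post_removal_profile(
    g: nx.Graph,
    i: Node,
    kshell: Mapping[Node, int] | None = None,
    bfs_cutoff: int | None = None,
) -> NeighborhoodProfile:
    """Remove ``i`` (non-destructively) and survey its neighborhood.

    Post-removal degrees and pairwise BFS distances are measured in the
    graph without ``i``; K-shells come from the intact graph (computed
    here if not supplied).  With ``bfs_cutoff`` set, neighbor pairs
    farther apart than the cutoff are recorded as UNREACHABLE — an
    explicit approximation, off by default.
    """
    if i not in g:
        raise GraphDomainError(f"node {i!r} not in graph")
    nbrs = _neighbors_sorted(g, i)
    if kshell is None:
        kshell = k_shell(g).kshell
    residual = remove_node_view(g, i)
    post_distance: dict[tuple[Node, Node], object] = {}
    for n in nbrs:
        dists = bfs_distances(residual, n, targets=nbrs, cutoff=bfs_cutoff)
        for j in nbrs:
            if j != n:
                post_distance[(n, j)] = dists[j]
    return NeighborhoodProfile(
        center=i,
        neighbors=nbrs,
        pre_degree={j: g.degree(j) for j in nbrs},
        post_degree={j: residual.degree(j) for j in nbrs},
        kshell={j: kshell[j] for j in nbrs},
        post_distance=post_distance,
    )


def fitting_distribution(
    profile: NeighborhoodProfile, floor: float = DEFAULT_FLOOR
) -> FittingDistribution:
    """Q_i from a neighborhood profile.

    Row *n*, column *j* carries ``sqrt(λ(n,j)) · d'(j)`` normalized over
    the row; the row owner's own slot uses λ = 1.  A post-removal degree
    of zero is replaced by ``floor`` before normalization so the row
    remains a valid distribution.

    Raises
    ------
    DegenerateDistributionError
        If a row's raw weights are all zero (only with ``floor=0``).
    """
    nbrs = profile.neighbors
    k = len(nbrs)
    if k < 1:
        raise GraphDomainError("profile has no neighbors")
    rows = np.empty((k, k), dtype=float)
    post_deg = np.array(
        [profile.post_degree[j] or floor for j in nbrs], dtype=float
    )
    for a, n in enumerate(nbrs):
        lam = np.array(
            [
                path_change_factor(SELF if j == n else profile.post_distance[(n, j)])
                for j in nbrs
            ]
        )
        weights = np.sqrt(lam) * post_deg
        total = weights.sum()
        if total <= 0:
            raise DegenerateDistributionError(
                f"row for neighbor {n!r} of center {profile.center!r} has "
                f"all-zero weights; use a positive floor"
            )
        rows[a] = weights / total
    return FittingDistribution(profile.center, nbrs, rows)


def kl_divergence(
    p: RealDistribution | Sequence[float] | np.ndarray,
    q_row: Sequence[float] | np.ndarray,
    log_base: float = DEFAULT_LOG_BASE,
    floor: float = DEFAULT_FLOOR,
) -> float:
    """D(P || q) = Σ_x P(x) · log_base(P(x) / q(x)).

    Terms with P(x) = 0 contribute nothing; q entries are clamped to
    ``floor`` so the divergence stays finite.  Base 10 by default.
    """
    p_arr = p.probs if isinstance(p, RealDistribution) else np.asarray(p, float)
    q_arr = np.asarray(q_row, dtype=float)
    if p_arr.shape != q_arr.shape:
        raise GraphDomainError(
            f"distribution length mismatch: {p_arr.shape} vs {q_arr.shape}"
        )
    q_arr = np.maximum(q_arr, floor)
    mask = p_arr > 0
    terms = p_arr[mask] * np.log(p_arr[mask] / q_arr[mask])
    return float(terms.sum() / math.log(log_base))


def _divergence_terms(
    g: nx.Graph,
    i: Node,
    kshell: Mapping[Node, int] | None,
    log_base: float,
    floor: float,
    bfs_cutoff: int | None,
) -> tuple[NeighborhoodProfile, dict[Node, float]]:
    """Per-neighbor D'_ij for center i (helper shared by the public ops)."""
    profile = post_removal_profile(g, i, kshell=kshell, bfs_cutoff=bfs_cutoff)
    p = real_distribution(g, i)
    q = fitting_distribution(profile, floor=floor)
    d_rows = {
        j: kl_divergence(p, q.rows[a], log_base=log_base, floor=floor)
        for a, j in enumerate(profile.neighbors)
    }
    return profile, d_rows


def node_divergence(
    g: nx.Graph,
    i: Node,
    kshell: Mapping[Node, int] | None = None,
    log_base: float = DEFAULT_LOG_BASE,
    floor: float = DEFAULT_FLOOR,
    bfs_cutoff: int | None = None,
) -> float:
    """D_i = Σ_{j∈Γ(i)} Kshell(j) · D'_ij, shells from the intact graph."""
    profile, d_rows = _divergence_terms(g, i, kshell, log_base, floor, bfs_cutoff)
    return float(sum(profile.kshell[j] * d_rows[j] for j in profile.neighbors))


def damage_influence(
    g: nx.Graph,
    i: Node,
    kshell: Mapping[Node, int] | None = None,
    log_base: float = DEFAULT_LOG_BASE,
    floor: float = DEFAULT_FLOOR,
    bfs_cutoff: int | None = None,
) -> float:
    """DE(i) = D_i + d(i); zero for isolated nodes."""
    if i not in g:
        raise GraphDomainError(f"node {i!r} not in graph")
    if g.degree(i) == 0:
        return 0.0
    return node_divergence(g, i, kshell, log_base, floor, bfs_cutoff) + g.degree(i)


def kln_score(
    g: nx.Graph,
    i: Node,
    de: Mapping[Node, float] | None = None,
    log_base: float = DEFAULT_LOG_BASE,
    floor: float = DEFAULT_FLOOR,
    bfs_cutoff: int | None = None,
) -> float:
    """KLN(i) = DE(i) + sqrt(Σ_{j∈Γ(i)} DE(j)); zero for isolated nodes.

    Pass a precomputed ``de`` mapping to avoid recomputing neighbor
    damage influences (as :func:`rank_all` does).
    """
    if i not in g:
        raise GraphDomainError(f"node {i!r} not in graph")
    if g.degree(i) == 0:
        return 0.0
    if de is None:
        kshell = k_shell(g).kshell
        needed = [i, *g.neighbors(i)]
        de = {
            v: damage_influence(g, v, kshell, log_base, floor, bfs_cutoff)
            for v in needed
        }
    return de[i] + math.sqrt(sum(de[j] for j in g.neighbors(i)))


def rank_all(
    g: nx.Graph,
    log_base: float = DEFAULT_LOG_BASE,
    floor: float = DEFAULT_FLOOR,
    bfs_cutoff: int | None = None,
) -> ScoreTable:
    """Score every node and rank by KLN descending.

    Damage influences are computed once per node and reused across the
    neighborhood sums.  Ties are broken by ascending node identifier, so
    the ranking is deterministic.
    """
    shells = k_shell(g).kshell
    kl: dict[Node, float] = {}
    de: dict[Node, float] = {}
    for v in g.nodes():
        if g.degree(v) == 0:
            kl[v] = 0.0
            de[v] = 0.0
        else:
            kl[v] = node_divergence(g, v, shells, log_base, floor, bfs_cutoff)
            de[v] = kl[v] + g.degree(v)
    kln = {
        v: 0.0
        if g.degree(v) == 0
        else de[v] + math.sqrt(sum(de[j] for j in g.neighbors(v)))
        for v in g.nodes()
    }
    ranking = tuple(sorted(g.nodes(), key=lambda v: (-kln[v], v)))
    return ScoreTable(
        kl=kl,
        de=de,
        kln=kln,
        degree={v: d for v, d in g.degree()},
        kshell=shells,
        ranking=ranking,
    )
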