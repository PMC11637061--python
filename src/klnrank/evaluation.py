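"""Ranking-comparison metrics.

Kendall tau concordance against the SIR oracle, top-N overlap between
rankings, capacity-by-rank curves (with a roughness count), and the
rank-tier management classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import GraphDomainError
from .graph import Node

__all__ = [
    "KendallResult",
    "TierAssignment",
    "kendall_tau",
    "top_n_overlap",
    "capacity_by_rank",
    "management_tiers",
    "DEFAULT_TIER_BOUNDARIES",
]

#: Rank cut points of the four-tier management scheme (top 30 primary,
#: 31-183 secondary, 184-248 tertiary, 249-382 quaternary, rest ordinary).
DEFAULT_TIER_BOUNDARIES = (30, 183, 248, 382)


@dataclass(frozen=True)
class KendallResult:
    """tau = (a - b) / (0.5 n (n-1)) with exact pair counts.

    ``a`` counts concordant pairs, ``b`` discordant; pairs tied in
    either sequence contribute to neither.
    """

    tau: float
    a: int
    b: int
    n: int


def kendall_tau(
    x: Mapping[Node, float], y: Mapping[Node, float], variant: str = "a"
) -> KendallResult:
    """Kendall rank correlation between two score mappings.

    Over all unordered key pairs, a pair is concordant when both
    mappings order it the same strict way and discordant when opposite;
    ties in either mapping are excluded from both counts.  The default
    variant "a" divides (a - b) by the full 0.5·n·(n-1); variant "b"
    divides by the geometric mean of tie-corrected pair counts.
    """
    if set(x) != set(y):
        raise GraphDomainError("score mappings must share the same key set")
    keys = sorted(x)
    n = len(keys)
    if n < 2:
        raise GraphDomainError("need at least 2 keys")
    xv = np.array([x[k] for k in keys], dtype=float)
    yv = np.array([y[k] for k in keys], dtype=float)
    # sign of every pairwise difference; O(n^2), fine for n up to ~10^4
    sx = np.sign(xv[:, None] - xv[None, :])
    sy = np.sign(yv[:, None] - yv[None, :])
    iu = np.triu_indices(n, k=1)
    prod = sx[iu] * sy[iu]
    a = int((prod > 0).sum())
    b = int((prod < 0).sum())
    if variant == "a":
        denom = 0.5 * n * (n - 1)
    elif variant == "b":
        n0 = n * (n - 1) / 2.0
        tx = int((sx[iu] == 0).sum())
        ty = int((sy[iu] == 0).sum())
        denom = np.sqrt((n0 - tx) * (n0 - ty))
        if denom == 0:
            raise GraphDomainError("tau-b undefined: a sequence is constant")
    else:
        raise GraphDomainError(f"unknown variant {variant!r}")
    return KendallResult(tau=float((a - b) / denom), a=a, b=b, n=n)


def top_n_overlap(
    rank_a: Sequence[Node], rank_b: Sequence[Node], n: int
) -> tuple[int, int]:
    """(shared, same-position) counts between two top-n lists.

    ``shared`` is the size of the intersection of the two top-n sets;
    ``same-position`` counts indices where the lists agree exactly.
    """
    if n > len(rank_a) or n > len(rank_b):
        raise GraphDomainError(
            f"n={n} exceeds a ranking length ({len(rank_a)}, {len(rank_b)})"
        )
    top_a, top_b = list(rank_a[:n]), list(rank_b[:n])
    shared = len(set(top_a) & set(top_b))
    same_pos = sum(1 for u, v in zip(top_a, top_b) if u == v)
    return shared, same_pos


def capacity_by_rank(
    ranking: Sequence[Node], capacity: Mapping[Node, float]
) -> tuple[list[float], int]:
    """Capacities in ranking order plus a roughness count.

    The roughness statistic counts upward violations of monotone
    decrease (positions where the next capacity exceeds the current
    one); a ranking that matches the capacity ordering scores 0.
    """
    missing = [v for v in ranking if v not in capacity]
    if missing:
        raise GraphDomainError(f"capacity missing for nodes: {missing[:5]}")
    seq = [float(capacity[v]) for v in ranking]
    violations = sum(1 for i in range(len(seq) - 1) if seq[i + 1] > seq[i])
    return seq, violations


@dataclass(frozen=True)
class TierAssignment:
    """Management tier per node; tier 1 is the highest-priority group."""

    boundaries: tuple[int, ...]
    labels: Mapping[Node, int]

    def tier_sizes(self) -> list[int]:
        n_tiers = len(self.boundaries) + 1
        sizes = [0] * n_tiers
        for t in self.labels.values():
            sizes[t - 1] += 1
        return sizes


def management_tiers(
    ranking: Sequence[Node],
    boundaries: Sequence[int] = DEFAULT_TIER_BOUNDARIES,
) -> TierAssignment:
    """Cut a ranking into management tiers at 1-based rank boundaries.

    Ranks 1..b1 get tier 1, b1+1..b2 tier 2, ..., and everything past
    the last boundary falls into the final tier (possibly empty).
    """
    bounds = tuple(int(b) for b in boundaries)
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])) or (
        bounds and bounds[0] < 1
    ):
        raise GraphDomainError(f"boundaries must be strictly increasing: {bounds}")
    if bounds and bounds[-1] > len(ranking):
        raise GraphDomainError(
            f"boundary {bounds[-1]} exceeds ranking length {len(ranking)}"
        )
    labels: dict[Node, int] = {}
    for pos, node in enumerate(ranking, start=1):
        tier = len(bounds) + 1
        for t, b in enumerate(bounds, start=1):
            if pos <= b:
                tier = t
                break
        labels[node] = tier
    return TierAssignment(bounds, labels)
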