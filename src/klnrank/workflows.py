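"""High-level, reproducible runs tying the modules together.

These functions are the package's scripting surface (the examples/
directory drives them): rank a graph by any method, run the SIR oracle,
compare rankings, cut management tiers, and write every table as CSV
with a provenance header (tool version, resolved configuration, input
digest) so a result file is self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from . import __version__
from .centrality import degree_centrality, eigenvector_centrality, k_shell, pagerank
from .errors import GraphDomainError
from .evaluation import (
    DEFAULT_TIER_BOUNDARIES,
    capacity_by_rank,
    kendall_tau,
    management_tiers,
    top_n_overlap,
)
from .graph import Node
from .kln import DEFAULT_FLOOR, DEFAULT_LOG_BASE, rank_all
from .sir import SIRConfig, spreading_capacity, topn_infection_curve

logger = logging.getLogger(__name__)

METHODS = ("kln", "dc", "kshell", "ec", "pr")


@dataclass(frozen=True)
class RunConfig:
    """Resolved knobs for a reproducible run; echoed into output headers."""

    log_base: float = DEFAULT_LOG_BASE
    degree_floor: float = DEFAULT_FLOOR
    bfs_cutoff: int | None = None
    sir_alpha: float = 0.1
    sir_beta: float = 1.0
    sir_iterations: int = 1000
    sir_rounds: int = 30
    rng_seed: int = 0
    tier_boundaries: tuple[int, ...] = DEFAULT_TIER_BOUNDARIES

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tier_boundaries"] = list(self.tier_boundaries)
        return d

    def sir_config(self, **overrides) -> SIRConfig:
        kwargs = dict(
            alpha=self.sir_alpha,
            beta=self.sir_beta,
            max_rounds=self.sir_rounds,
            iterations=self.sir_iterations,
            rng_seed=self.rng_seed,
        )
        kwargs.update(overrides)
        return SIRConfig(**kwargs)


def _provenance_header(config: RunConfig, inputs: Mapping[str, str]) -> str:
    lines = [f"# klnrank {__version__}"]
    lines.append(f"# config: {json.dumps(config.as_dict(), sort_keys=True)}")
    for name, digest in inputs.items():
        lines.append(f"# input {name}: {digest}")
    return "\n".join(lines) + "\n"


def graph_digest(g: nx.Graph) -> str:
    """Order-independent sha256 over the sorted edge set."""
    payload = "\n".join(
        f"{min(str(u), str(v))}\t{max(str(u), str(v))}" for u, v in g.edges()
    )
    edges = sorted(payload.split("\n")) if payload else []
    h = hashlib.sha256("\n".join(edges).encode()).hexdigest()
    return f"sha256:{h[:16]}"


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config: RunConfig,
    inputs: Mapping[str, str] | None = None,
) -> Path:
    """Write a CSV with the provenance header; read back with comment='#'."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(config, inputs or {}))
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def rank_table(
    g: nx.Graph, method: str = "kln", config: RunConfig = RunConfig()
) -> pd.DataFrame:
    """Rank every node by one method.

    KLN yields columns node,kln,de,d,kshell,rank; the baselines yield
    node,method,score(,shell),rank.  Ordering: score descending, ties
    by ascending node identifier.
    """
    if method == "kln":
        table = rank_all(
            g,
            log_base=config.log_base,
            floor=config.degree_floor,
            bfs_cutoff=config.bfs_cutoff,
        )
        return table.to_frame()
    if method == "dc":
        cs = degree_centrality(g)
    elif method == "kshell":
        cs = k_shell(g)
    elif method == "ec":
        cs = eigenvector_centrality(g)
    elif method == "pr":
        cs = pagerank(g)
    else:
        raise GraphDomainError(f"unknown method {method!r}; choose from {METHODS}")
    order = cs.ranking()
    df = pd.DataFrame(
        {
            "node": order,
            "method": method,
            "score": [cs.scores[v] for v in order],
        }
    )
    if cs.kshell:
        df["shell"] = [cs.kshell[v] for v in order]
    df["rank"] = range(1, len(order) + 1)
    return df


def capacity_table(
    g: nx.Graph, config: RunConfig = RunConfig()
) -> pd.DataFrame:
    """Per-node SIR spreading capacity: node,capacity,stderr."""
    res = spreading_capacity(g, config.sir_config(max_rounds=0))
    nodes = sorted(res.capacity)
    return pd.DataFrame(
        {
            "node": nodes,
            "capacity": [res.capacity[v] for v in nodes],
            "stderr": [res.capacity_stderr[v] for v in nodes],
        }
    )


def curve_table(
    g: nx.Graph, seed_set: Sequence[Node], config: RunConfig = RunConfig()
) -> pd.DataFrame:
    """F(t) curve for a seed set: t,F_mean,F_stderr."""
    res = topn_infection_curve(g, seed_set, config.sir_config())
    return pd.DataFrame(
        {
            "t": range(len(res.curve)),
            "F_mean": res.curve,
            "F_stderr": res.curve_stderr,
        }
    )


def top_seeds(ranking_df: pd.DataFrame, n: int) -> list:
    """The top-n node column of a ranking table (seed spec ``top:N``)."""
    if n > len(ranking_df):
        raise GraphDomainError(f"top:{n} exceeds ranking length {len(ranking_df)}")
    return list(ranking_df["node"].iloc[:n])


def compare_rankings(
    rankings: Mapping[str, pd.DataFrame],
    capacity: Mapping[Node, float] | None = None,
    n: int = 10,
) -> pd.DataFrame:
    """Pairwise comparison of ranking tables.

    Emits one row per unordered method pair with columns
    method_a,method_b,n,shared,same_position,tau; with a capacity
    mapping, a per-method ``violations`` roughness column is appended
    (upward breaks of monotone decrease in capacity-by-rank order).
    """
    names = sorted(rankings)
    universes = {m: set(rankings[m]["node"]) for m in names}
    base = universes[names[0]]
    offenders = {m: universes[m] ^ base for m in names if universes[m] != base}
    if offenders:
        raise GraphDomainError(f"rankings disagree on the node universe: {offenders}")

    def scores(m: str) -> dict:
        df = rankings[m]
        col = "kln" if "kln" in df.columns else "score"
        return dict(zip(df["node"], df[col]))

    rows = []
    for i, ma in enumerate(names):
        for mb in names[i + 1 :]:
            shared, same = top_n_overlap(
                list(rankings[ma]["node"]), list(rankings[mb]["node"]), n
            )
            tau = kendall_tau(scores(ma), scores(mb)).tau
            rows.append(
                {
                    "method_a": ma,
                    "method_b": mb,
                    "n": n,
                    "shared": shared,
                    "same_position": same,
                    "tau": tau,
                }
            )
    df = pd.DataFrame(rows)
    if capacity is not None:
        viol = {
            m: capacity_by_rank(list(rankings[m]["node"]), capacity)[1]
            for m in names
        }
        df["violations_a"] = df["method_a"].map(viol)
        df["violations_b"] = df["method_b"].map(viol)
    return df


def tiers_table(
    ranking_df: pd.DataFrame, config: RunConfig = RunConfig()
) -> pd.DataFrame:
    """Management-tier cut of a ranking: node,rank,tier."""
    order = list(ranking_df["node"])
    assignment = management_tiers(order, config.tier_boundaries)
    return pd.DataFrame(
        {
            "node": order,
            "rank": range(1, len(order) + 1),
            "tier": [assignment.labels[v] for v in order],
        }
    )
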