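"""Discrete-time SIR spreading simulator.

Serves as the ground-truth influence oracle: a node's spreading
capacity is the mean final outbreak size (|I| + |R| at extinction) when
it seeds an epidemic alone.

Dynamics per round (synchronous): every infected node independently
infects each susceptible neighbor with probability ``alpha``, then
recovers with probability ``beta``.  Infection precedes recovery within
the round, so even with ``beta = 1`` an infected node transmits for
exactly one round — the convention the beta = 1 experiments require.
Recovered nodes never re-enter S or I.

Each Monte-Carlo replicate gets its own RNG stream seeded
``rng_seed + replicate``, so growing the replicate count never perturbs
earlier replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import GraphDomainError
from .graph import Node

__all__ = ["SIRConfig", "Trajectory", "SpreadResult", "sir_run",
           "spreading_capacity", "topn_infection_curve"]


@dataclass(frozen=True)
class SIRConfig:
    """Parameters of one SIR experiment.

    alpha : per-contact infection probability per round, in [0, 1].
    beta : per-round recovery probability, in (0, 1].
    seeds : initially infected nodes.
    max_rounds : round cap; 0 means run to extinction.
    iterations : Monte-Carlo replicate count (default 1000).
    rng_seed : base seed; replicate r uses stream rng_seed + r.
    """

    alpha: float
    beta: float = 1.0
    seeds: tuple[Node, ...] = ()
    max_rounds: int = 0
    iterations: int = 1000
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise GraphDomainError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 < self.beta <= 1.0:
            raise GraphDomainError(f"beta must be in (0, 1], got {self.beta}")
        if self.iterations < 1:
            raise GraphDomainError("iterations must be >= 1")
        if self.max_rounds < 0:
            raise GraphDomainError("max_rounds must be >= 0")
        object.__setattr__(self, "seeds", tuple(self.seeds))


@dataclass(frozen=True)
class Trajectory:
    """One replicate: per-round states (after the round's updates).

    ``history[0]`` is the initial state; ``history[t]`` the state after
    round t.  ``final_size`` counts every node ever infected
    (|I| + |R| at termination).
    """

    history: tuple[tuple[frozenset, frozenset, frozenset], ...]
    final_size: int

    @property
    def rounds(self) -> int:
        return len(self.history) - 1

    def ever_infected_counts(self) -> list[int]:
        return [len(i) + len(r) for _, i, r in self.history]


@dataclass(frozen=True)
class SpreadResult:
    """Aggregated Monte-Carlo output.

    Per-node mode fills ``capacity``/``capacity_stderr``/``finals``;
    seed-set mode fills the F(t) ``curve`` and ``curve_stderr``.
    """

    capacity: Mapping[Node, float] = field(default_factory=dict)
    capacity_stderr: Mapping[Node, float] = field(default_factory=dict)
    finals: Mapping[Node, np.ndarray] = field(default_factory=dict)
    curve: np.ndarray | None = None
    curve_stderr: np.ndarray | None = None

    def ranking(self) -> list[Node]:
        return sorted(self.capacity, key=lambda v: (-self.capacity[v], v))


def sir_run(g: nx.Graph, cfg: SIRConfig, replicate: int = 0) -> Trajectory:
    """Run one replicate; fully reproducible from cfg.rng_seed + replicate."""
    if not cfg.seeds:
        raise GraphDomainError("seed set is empty")
    for s in cfg.seeds:
        if s not in g:
            raise GraphDomainError(f"seed {s!r} not in graph")
    rng = np.random.default_rng(cfg.rng_seed + replicate)
    infected = set(cfg.seeds)
    recovered: set[Node] = set()
    susceptible = set(g.nodes()) - infected
    history = [(frozenset(susceptible), frozenset(infected), frozenset(recovered))]
    rounds = 0
    while infected and (cfg.max_rounds == 0 or rounds < cfg.max_rounds):
        newly_infected: set[Node] = set()
        for u in sorted(infected):
            for v in sorted(g.neighbors(u)):
                if v in susceptible and v not in newly_infected:
                    if rng.random() < cfg.alpha:
                        newly_infected.add(v)
        newly_recovered = {u for u in sorted(infected) if rng.random() < cfg.beta}
        susceptible -= newly_infected
        infected = (infected | newly_infected) - newly_recovered
        recovered |= newly_recovered
        rounds += 1
        history.append(
            (frozenset(susceptible), frozenset(infected), frozenset(recovered))
        )
    return Trajectory(tuple(history), len(infected) + len(recovered))


def _final_sizes(g: nx.Graph, cfg: SIRConfig) -> np.ndarray:
    return np.array(
        [sir_run(g, cfg, replicate=r).final_size for r in range(cfg.iterations)],
        dtype=float,
    )


def spreading_capacity(
    g: nx.Graph, cfg: SIRConfig, nodes: Iterable[Node] | None = None
) -> SpreadResult:
    """Mean final outbreak size per node, each node seeding alone.

    ``cfg.seeds`` is ignored; each node in ``nodes`` (default: all) is
    used as the sole seed for ``cfg.iterations`` replicates.
    """
    if nodes is None:
        nodes = g.nodes()
    capacity: dict[Node, float] = {}
    stderr: dict[Node, float] = {}
    finals: dict[Node, np.ndarray] = {}
    for v in sorted(nodes):
        sizes = _final_sizes(g, replace(cfg, seeds=(v,)))
        finals[v] = sizes
        capacity[v] = float(sizes.mean())
        stderr[v] = float(sizes.std(ddof=1) / math.sqrt(len(sizes))) if len(sizes) > 1 else 0.0
    return SpreadResult(capacity=capacity, capacity_stderr=stderr, finals=finals)


def topn_infection_curve(
    g: nx.Graph, seed_set: Sequence[Node], cfg: SIRConfig
) -> SpreadResult:
    """F(t): mean cumulative ever-infected count after each round.

    t runs 0..max_rounds (default 30 when ``cfg.max_rounds`` is 0); once
    an epidemic goes extinct its count stays flat.  F(0) = |seed_set|.
    """
    seeds = tuple(seed_set)
    if not seeds:
        raise GraphDomainError("seed set is empty")
    rounds = cfg.max_rounds if cfg.max_rounds > 0 else 30
    run_cfg = replace(cfg, seeds=seeds, max_rounds=rounds)
    counts = np.empty((cfg.iterations, rounds + 1), dtype=float)
    for r in range(cfg.iterations):
        traj = sir_run(g, run_cfg, replicate=r)
        ever = traj.ever_infected_counts()
        # pad post-extinction rounds with the final cumulative count
        ever += [ever[-1]] * (rounds + 1 - len(ever))
        counts[r] = ever
    mean = counts.mean(axis=0)
    if cfg.iterations > 1:
        se = counts.std(axis=0, ddof=1) / math.sqrt(cfg.iterations)
    else:
        se = np.zeros(rounds + 1)
    return SpreadResult(curve=mean, curve_stderr=se)
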