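"""Independent brute-force reference implementations used as oracles.

Deliberately shares no code path with the package: its own K-shell
peeling loop, Floyd-Warshall all-pairs distances via scipy, and naive
per-formula loops for the KLN chain.
"""

import math

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import floyd_warshall


def ref_kshell(g: nx.Graph) -> dict:
    """Core numbers by literal iterative peeling."""
    h = g.copy()
    shells = {v: 0 for v in g.nodes()}
    k = 0
    while h.number_of_nodes() > 0:
        stripped_any = True
        while stripped_any:
            batch = [v for v, d in h.degree() if d <= k]
            stripped_any = bool(batch)
            for v in batch:
                shells[v] = k
                h.remove_node(v)
        k += 1
    return shells


def ref_all_pairs(g: nx.Graph) -> dict:
    """All-pairs hop counts via dense Floyd-Warshall; inf = unreachable."""
    nodes = sorted(g.nodes())
    idx = {v: a for a, v in enumerate(nodes)}
    mat = np.full((len(nodes), len(nodes)), np.inf)
    np.fill_diagonal(mat, 0.0)
    for u, v in g.edges():
        mat[idx[u], idx[v]] = mat[idx[v], idx[u]] = 1.0
    dist = floyd_warshall(mat, directed=False)
    return {(u, v): dist[idx[u], idx[v]] for u in nodes for v in nodes}


def ref_de(g: nx.Graph, i, log_base=10.0, floor=1e-10) -> float:
    """Damage influence DE(i) by direct evaluation of every formula."""
    nbrs = sorted(g.neighbors(i))
    if not nbrs:
        return 0.0
    shells = ref_kshell(g)
    residual = g.copy()
    residual.remove_node(i)
    dist = ref_all_pairs(residual)
    deg_sum = sum(g.degree(j) for j in nbrs)
    p = [g.degree(j) / deg_sum for j in nbrs]
    d_i = 0.0
    for j in nbrs:  # KL of P against the fitted row owned by j
        weights = []
        for m in nbrs:
            if m == j:
                lam = 1.0
            else:
                l = dist[(j, m)]
                lam = 0.5 if math.isinf(l) else 1.0 / l
            dprime = residual.degree(m)
            weights.append(math.sqrt(lam) * (dprime if dprime > 0 else floor))
        total = sum(weights)
        q = [w / total for w in weights]
        kl = sum(
            pk * math.log(pk / max(qk, floor), log_base)
            for pk, qk in zip(p, q)
            if pk > 0
        )
        d_i += shells[j] * kl
    return d_i + g.degree(i)


def ref_kln_scores(g: nx.Graph) -> dict:
    de = {v: ref_de(g, v) for v in g.nodes()}
    return {
        v: 0.0
        if g.degree(v) == 0
        else de[v] + math.sqrt(sum(de[j] for j in g.neighbors(v)))
        for v in g.nodes()
    }


def enumerate_mean_outbreak(g: nx.Graph, seed, alpha: float) -> float:
    """Exact mean final SIR outbreak size for beta = 1 by branching over
    every infection outcome (small graphs only)."""

    def rec(frontier, infected):
        if not frontier:
            return float(len(infected))
        exposure: dict = {}
        for u in frontier:
            for v in g.neighbors(u):
                if v not in infected:
                    exposure[v] = exposure.get(v, 0) + 1
        items = sorted(exposure.items(), key=lambda kv: str(kv[0]))
        total = 0.0
        for bits in range(2 ** len(items)):
            prob = 1.0
            newly = set()
            for pos, (v, k) in enumerate(items):
                p_inf = 1.0 - (1.0 - alpha) ** k
                if (bits >> pos) & 1:
                    prob *= p_inf
                    newly.add(v)
                else:
                    prob *= 1.0 - p_inf
            if prob > 0:
                total += prob * rec(frozenset(newly), infected | newly)
        return total

    return rec(frozenset([seed]), frozenset([seed]))
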