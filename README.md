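# klnrank

Influential-node ranking for undirected networks by **Kullback–Leibler
divergence within the neighborhood** (KLN), with the classical baseline
centralities, a discrete-time SIR spreading simulator as a ground-truth
influence oracle, and ranking-comparison metrics.

## The problem

In epidemic contact networks, information-dissemination networks, and
distributed systems alike, a few nodes matter disproportionately:
removing (or vaccinating, or protecting) them changes how everything
else communicates. Classical centralities score nodes on a *static*
picture — degree counts neighbors, K-shell measures coreness — and miss
what actually happens when a node fails. KLN scores a node by
simulating exactly that failure and measuring the information-entropy
loss it inflicts on its own neighborhood.

## The model

For a simple undirected graph `G = (V, E)` with neighbor sets `Γ(i)`,
degree `d(i)`, and K-shell `Kshell(i)`:

**Real distribution.** While `i` is intact, its neighbors receive
information in proportion to their degree:

    p_i(j) = d(j) / Σ_{j∈Γ(i)} d(j)

**Fitting distribution.** Remove `i`. Each neighbor `n` now reaches the
other neighbors only through the remaining graph. With `l(n,j)` the
post-removal shortest hop distance, the path change factor is
`λ(n,j) = 1/l(n,j)` — set to `1/2` when `n` and `j` are disconnected
(they previously communicated through `i` in two hops) and to `1` for
the row owner's own slot. With `d′(j)` the post-removal degree:

    χ_in(j) = √λ(n,j)·d′(j) / Σ_{j∈Γ(i)} √λ(n,j)·d′(j)

**KL loss and scores.** Each fitted row is compared to the real
distribution with base-10 logarithms, weighted by intact-graph shells,
and combined with degree and the neighborhood's pooled damage:

    D′_ij = Σ_x P_i(x)·log10(P_i(x)/q_ij(x))
    D_i   = Σ_{j∈Γ(i)} Kshell(j)·D′_ij
    DE(i) = D_i + d(i)
    KLN(i) = DE(i) + √(Σ_{j∈Γ(i)} DE(j))

Nodes are ranked by KLN descending. `DE(i) ≥ d(i)` and
`KLN(i) ≥ DE(i)` always; isolated nodes score 0.

## Worked example

`python examples/worked_example.py` walks the scoring chain on the
packaged 13-node, 18-edge demonstration network, removing node 1
(degree 4, shell 2, neighbors 2, 6, 7, 8):

```
P_1 (degree-proportional dissemination probabilities): [0.385 0.231 0.154 0.231]

after removing node 1:
  post-removal degrees: {2: 4, 6: 2, 7: 1, 8: 2}
  fitted rows Q_1 (one per neighbor; how dissemination looks now):
    q_12 = [0.533 0.267 0.067 0.133]   KL loss D'_12 = 0.042
    q_16 = [0.517 0.259 0.075 0.149]   KL loss D'_16 = 0.031
    q_17 = [0.359 0.207 0.18  0.254]   KL loss D'_17 = 0.002
    q_18 = [0.341 0.197 0.121 0.341]   KL loss D'_18 = 0.013

shell-weighted divergence D_1 = 0.218 (neighbor shells [3, 2, 2, 2])
damage influence DE(1) = D_1 + d(1) = 4.218
```

Reading it: node 2's fitted row (`q_12`) diverges most from `P_1` —
after node 1 fails, node 2 suddenly finds neighbor 7 four hops away
instead of two, so information routed through node 2's corner of the
neighborhood loses the most entropy (`D'_12 = 0.042`). Weighting each
loss by the neighbor's coreness and adding node 1's own degree gives
its damage influence, 4.218.

Other entry points:

- `examples/rank_and_compare.py` — KLN vs. degree, K-shell,
  eigenvector, and PageRank rankings on a scale-free graph; Kendall τ
  and top-10 overlap.
- `examples/sir_capacity.py` — validates a ranking against SIR
  spreading capacity (mean single-seed outbreak size) and plots the
  F(t) curve data for the top-10 seed set.
- `examples/management_tiers.py` — cuts a 1204-node ranking into
  priority tiers (30/153/65/134/822) for staged intervention.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds the packaged demonstration network from its edge list and
recomputes, from scratch, the eight intermediate quantities of the
worked example above — the real-distribution entry for neighbor 2, two
entries of fitted row `q_17`, one of `q_12`, the KL losses for
neighbors 6 and 7, the shell-weighted divergence `D_1`, and the damage
influence `DE(1)` — writing each (rounded to 3 decimals) as JSON. All
quantities are deterministic.
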