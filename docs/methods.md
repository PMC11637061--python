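# Methods

## The KLN score

KLN treats node importance as a counterfactual: remove the node,
and measure how badly information dissemination degrades *within its
own one-hop neighborhood*. The degradation is an information-entropy
loss — the KL divergence between how the neighbors shared information
while the node was intact (the *real* distribution, degree-
proportional) and how they can share it afterwards (the *fitting*
distribution, reweighted by post-removal distances and degrees). The
chain is described in the README; this note records the conventions,
parameters, and design choices behind it.

### Conventions the worked example forces

Several details are underdetermined by the defining formulas alone but
are pinned down by requiring the package to reproduce the hand-worked
demonstration exactly:

- **Logarithm base is 10.** Recomputing the demonstration's KL terms
  from its own printed distributions yields 0.042/0.031/0.002/0.013
  only in base 10; natural logarithms give values on a visibly
  different scale. Exposed as `log_base` everywhere; default 10.
- **The self slot of each fitted row** uses path change factor
  λ = 1 together with the row owner's *post-removal* degree (the
  demonstration's self term is `1·1` for a neighbor left with one
  edge). Distances to self are therefore never computed; the `SELF`
  marker encodes the convention.
- **d′(j) is the degree after removal.** One printed denominator term
  in the demonstration reads `√(1/3)·3` where only `√(1/3)·2` is
  consistent with the printed row value 0.359 and with d′(6) = d(6) − 1;
  the package implements the post-removal reading throughout.
- **K-shells in the weighting are taken from the intact graph**,
  computed once and reused for every center (the demonstration weights
  with the full-graph shells). They are *not* recomputed per removal.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `log_base` | 10 | base of the KL logarithm (dimensionless score scale) |
| `floor` / `degree_floor` | 1e-10 | stand-in for a post-removal degree of 0 |
| `bfs_cutoff` | off | optional hop limit on post-removal BFS |

**The degree floor.** If removing `i` strands a leaf neighbor entirely
(`d′(j) = 0`), the fitted columns for `j` would be zero and the KL loss
infinite. The floor replaces 0 by 1e-10 before normalization: rows stay
valid distributions and losses become large but finite, which preserves
the intended "maximal damage" reading — nodes whose failure isolates a
neighbor rank very high. Raising the floor softens that emphasis.

**The BFS cutoff.** Exact post-removal distances require a BFS per
neighbor per removal, which dominates the cost on dense or large
graphs. With a cutoff, pairs farther apart than the cutoff are treated
as disconnected (λ = 1/2) — an explicit approximation, off by default,
and the *only* other circumstance in which λ = 1/2 is used.

**Ties** in the final ranking are broken by ascending node identifier,
so output is deterministic. Automorphically equivalent nodes receive
exactly equal scores and adjacent ranks.

**Degenerate inputs.** Isolated nodes have DE = KLN = 0 and sort last
(by identifier). Degree-1 nodes have single-entry distributions, hence
zero divergence and DE = 1 exactly.

## Baselines

Degree centrality `d(i)/(N−1)`, K-shell (standard core number),
eigenvector centrality (power iteration, uniform start, tol 1e-8, unit
Euclidean norm), and PageRank (uniform teleport, damping 0.85). The
reference experiments never state the eigenvector/PageRank
parameterizations, so these are standard-parameter baselines, not
reproductions. networkx provides the numerics.

## SIR oracle

Synchronous discrete-time SIR: per round, every infected node
independently infects each susceptible neighbor with probability α,
then recovers with probability β. Infection precedes recovery within
the round, so with β = 1 each infected node transmits for exactly one
round — without this ordering the β = 1 experiments could not spread at
all. "Spreading capacity" is the mean *final cumulative outbreak size*
(|I| + |R| at extinction) over Monte-Carlo replicates (default 1000),
each node seeding alone; the F(t) curve reports the mean ever-infected
count per round (default horizon 30 rounds, defaults α = 0.1, β = 1).
Replicate `r` draws from an RNG stream seeded `rng_seed + r`, so
enlarging the replicate count never perturbs earlier replicates.

## Ranking comparison

Kendall τ is computed as `(a − b) / (0.5·n·(n−1))` with exact pair
counts on the raw score vectors; pairs tied in either vector count as
neither concordant nor discordant while the denominator stays full
(τ-a). Consequently a ranking compared against itself scores below 1
precisely when it contains ties — a feature, since heavy tying (e.g.
K-shell's coarse shells) *should* depress agreement. A τ-b variant
(tie-corrected denominator) is available but not default. Top-N
overlap reports both shared membership and same-position counts;
capacity-by-rank reports the capacities in ranking order plus a
roughness count (upward breaks of monotone decrease). Management tiers
cut a ranking at 1-based boundaries, default (30, 183, 248, 382).

## The packaged demonstration network

The hand-worked example's figure is not published as data, and its
caption (14 nodes, 18 edges) cannot be reconciled with every printed
quantity by any graph recoverable from the text alone. The packaged
fixture is therefore a 13-node, 18-edge *synthetic reconstruction*
whose node-1 neighborhood reproduces every printed quantity — neighbor
degrees (5, 3, 2, 3), shells (3, 2, 2, 2), the real distribution, all
four fitted rows, the KL terms, D₁ = 0.218, DE(1) = 4.218, and the
post-removal distances (4, 3, 2) from node 7. `validate_worked_example`
re-derives all of these on every test run; labels outside that
neighborhood are arbitrary. Published *full-network* scores (e.g. the
final ranking table of the original 14-node example) are consequently
not reproducible here and are not claimed: on this reconstruction,
node 1's printed intermediate chain holds exactly while its full-graph
KLN differs, and the final-score formula applied to the printed
component values yields 7.818, not the published 7.826 (the components
are evidently rounded).

## Synthetic data

Property tests run on Erdős–Rényi, Barabási–Albert, and Watts–Strogatz
generators (networkx conventions; BA yields `(n−m)·m` edges). These
provide topology variety and exact invariant checks — row
normalization, Gibbs non-negativity, brute-force equivalence,
isomorphism invariance — but they do not emulate the community
structure, degree inhomogeneity, or scale of real contact networks, so
a green suite establishes correctness of the computation, not field
performance of the ranking.

## Known limitations

- Undirected, unweighted, simple graphs only.
- Exact post-removal BFS makes worst-case cost higher than the nominal
  O(⟨k⟩²n) of the scoring loop; the cutoff trades exactness for speed.
- The SIR oracle is synchronous-update Monte-Carlo; no continuous-time
  dynamics, no SIS/SEIR variants.
- τ is computed on scores, not rank positions (identical under τ-a in
  the absence of ties).
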