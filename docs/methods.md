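# Methods

## Model and procedure

### Collective influence and adaptive dismantling

The package treats an interactome as a simple undirected graph over opaque
protein identifiers. The collective influence of node *i* at radius ℓ is

    CI_i = (k_i − 1) · Σ_{j ∈ ∂Ball(i, ℓ)} (k_j − 1),

with ∂Ball(i, ℓ) the set of nodes at shortest-path distance exactly ℓ from
*i*. The quantity Σ_i CI_i is the energy whose minimization characterizes
optimal percolation — finding the minimum node set whose removal destroys
the giant component. The exact problem is NP-hard, and the percolation
theory behind the score assumes locally tree-like graphs, which interactomes
are not; the CI set produced here is therefore an approximation by
construction, and the package makes no optimality claim beyond the greedy
heuristic it implements:

1. find the largest connected component (LCC) of the residual network;
2. stop if its size is at or below `stop_threshold`;
3. compute CI for every LCC node on the residual network;
4. remove the highest-scoring node (ties: higher degree first, then
   lexicographically smaller ID) and repeat.

Because scores are always evaluated on the residual graph, the path-product
term that the general-ℓ energy carries is handled implicitly: removed nodes
are absent and cannot lie on any shortest path. Distances for ℓ ≥ 2 come
from a breadth-first search truncated at depth ℓ.

Tunables and defaults:

* **ℓ = 1** (neighbor shell). The radius the analysis is designed around;
  general ℓ is supported.
* **stop_threshold = 2** nodes. "The giant component has vanished" is not a
  numeric statement; a two-node component is no longer a giant component
  under any reading, and the CI-set size is sensitive to this choice, so it
  is an explicit parameter (CLI flag `--stop`).
* **batch_size = 1**: exact adaptive recalculation after every removal.
  Larger batches skip the refresh inside a batch — a documented
  approximation for very large networks, not the default.
* **Tie rule** `degree-lex` (score, then degree, then ID) — deterministic
  and hub-biased among equal scores; `lex` is available. With no tie rule
  stated anywhere for the underlying procedure, determinism was the
  deciding criterion.

Nodes outside the current LCC are never scored or removed. The removal log
records, per step, the node, its CI score at removal, and the LCC size
before and after, which yields the G(q) trajectory directly.

Two baselines support efficiency comparisons: adaptive highest-degree
removal (ties lexicographic) and uniformly random removal. The random
baseline draws from the current LCC — removals outside it cannot shrink
the giant component, so this only flatters the baseline and makes the
"CI is smaller" comparison conservative.

### Betweenness and bottlenecks

c_B(v) sums σ_st(v)/σ_st over unordered pairs of distinct connected nodes
(endpoints excluded; disconnected pairs contribute 0), computed exactly
with Brandes' algorithm. The ordered-pair convention would double every
score and cannot reorder nodes, so the cheaper unordered convention is
used; values are left unnormalized for the same reason. Bottlenecks are the
⌈fraction·N⌉ top-betweenness nodes (default fraction 0.2), boundary ties
broken lexicographically. Betweenness is computed on the full network as
given; callers who want the LCC restriction apply it first.

### Enrichment statistics

All tests share one null model: uniform resampling of a node set of fixed
size from the universe (the nodes of the network under analysis; every
input set is intersected with the universe first). Defaults: R = 10,000
randomizations; tests use smaller R.

* **Node-set enrichment.** f_obs = |group ∩ feature| / |group|; each round
  replaces the feature by a uniform random same-size subset and recomputes
  the fraction. The score is the **mean over rounds of the per-round
  log2-ratio** (not the log of the ratio of means). Under uniform
  resampling the intersection count is exactly
  Hypergeometric(N, |group|, |feature|), so the implementation samples
  counts from that distribution directly — statistically identical to
  materializing node subsets, and O(R) instead of O(R·N). The feature set
  is the randomized one here; for edge/link classes the marked set is
  randomized instead, matching which label each question randomizes.
* **Zero counts.** log2 is undefined when either count is zero in a round.
  A Haldane-style half-count correction replaces both fractions by
  (count + 0.5)/(n + 1) in exactly those rounds; every round stays finite,
  no rounds are discarded, and the bias vanishes for large groups.
* **p-values.** Add-one empirical estimator (1 + #extreme)/(R + 1).
  Two-sided for enrichment scores, with extremeness measured as deviation
  from the null mean: round r is extreme when
  |f_rand,r − mean(f_rand)| ≥ |f_obs − mean(f_rand)|. One-sided (greater)
  for the giant-component test, which is a directional connectivity claim.
  Degenerate identities (feature = universe; marked = all nodes) give
  score 0 and p = 1 exactly.
* **Edge / link classes.** Edges are classified by endpoint membership in
  the marked set (3 classes undirected, 4 for directed links); class counts
  sum to the edge/link count in every round. Per class the report is
  log2(observed / null-mean count) with the same half-count guard, plus the
  two-sided empirical p. Links with an endpoint outside the universe are
  dropped with a logged count. An empty link set is a valid input (all
  counts 0, p = 1).
* **No degree-preserving null, no multiple-testing correction** — the
  statistics are defined against uniform label resampling, and each
  annotation set is a standalone question.

### Conservation analysis

A node is conserved under an ortholog map iff it has ≥ 1 ortholog pair.
The conserved-node feature feeds the node-set enrichment directly. The
interolog network keeps exactly the edges with both endpoints conserved and
retains source-side IDs: the downstream overlap test compares against the
source CI set and needs one namespace, and projecting through a
many-to-many map would multiply edges with no principled one-to-one rule.
"Conserved CI" means a CI protein of the interolog network, computed with
the same ℓ and stopping rule as the source analysis. The overlap of source
CI and conserved-CI membership over the source node universe is tested with
a one-sided (greater) Fisher's exact test.

## Synthetic data: what it emulates, and what it does not

* **Networks** are preferential-attachment graphs: a complete seed graph on
  m+1 nodes, then each new node attaches to m distinct existing nodes with
  probability proportional to degree. This yields the two properties the
  analysis needs — a connected graph (the CI algorithm operates on the LCC)
  and a heavy-tailed degree distribution with the hub/low-degree mix that
  makes CI sets interesting. Edge count is exactly C(m+1,2) + m(n−m−1);
  node IDs are zero-padded ("P000001"…) so lexicographic tie-breaks are
  stable. Defaults n = 1000, m = 2 give a sparse hub-dominated topology of
  roughly interactome-like density at desk scale.
* **Annotations**: weighted sampling without replacement
  (Efraimidis–Spirakis keys), weight ρ on a target class. ρ is a *sampling
  weight* (an odds-type parameter); for experiments that must recover a
  known score of log2(ρ), `planted_feature` instead fixes the group-member
  count at round(ρ·s·g/N), making the risk ratio exactly ρ by construction.
* **Ortholog maps**: each node conserved independently with probability
  p_target (default 0.9) if in the target class, else p_other (default
  0.3) — a strong, detectable conservation contrast.
* **Directed links**: sources uniform over a pool, targets uniform over the
  network, self-links dropped.
* Every generator is a pure function of its config; one seeded generator
  per call, no global state.

What the generators do **not** emulate: co-complex cliquishness and other
motif structure, degree-correlated annotation biases (essential genes being
hubs for non-topological reasons), many-to-many ortholog fan-out,
assortative mixing, or false-positive/false-negative interaction noise. Passing
tests therefore demonstrate that the algorithms and statistics behave as
specified on networks with realistic degree heterogeneity — not that any
particular biological conclusion transfers to a given curated interactome.

## Numerical and testing choices

* Giant-component nulls run on a sparse adjacency matrix
  (scipy connected components) for speed; the observed value goes through
  the same routine so observed and null are always comparable.
* Component ties (equal maximal size) are broken by the component with the
  lexicographically smallest member — all stages are byte-deterministic
  given their seeds.
* Independent test oracles are deliberately naive: CI scores against a
  from-scratch BFS shell evaluation; betweenness against explicit
  enumeration of every shortest path on ≤ 8-node graphs; Fisher p against
  a direct hypergeometric tail sum over all 2×2 tables with total ≤ 40.
* Statistical properties are asserted at sizes where the sampling noise is
  far smaller than the asserted effect: null calibration with 200
  replicates at R = 1000 on a 1000-node universe (mean within 3 SE of 0,
  p-values uniform by KS); planted recovery within ±0.15 of log2 ρ at
  R = 5000; dismantling efficiency as an ordering of means over 10
  preferential-attachment replicates at N = 1000 (LCC target < 1% of N).
* The cross-species independence check relabels the second
  preferential-attachment network with a seeded random permutation:
  without relabeling, arrival order determines hubness in *both* graphs
  and the two CI sets would be spuriously correlated. The uniformity
  assertion uses the 1% Kolmogorov–Smirnov critical value for 50
  replicates (≈ 0.23).
* Problem sizes throughout (N = 500–1000 networks, R = 1000–5000 in tests)
  were chosen so the full suite runs in minutes on a single core while
  keeping every assertion's noise floor well below its tolerance.

## Known limitations

* The greedy CI heuristic has no optimality guarantee, and no reinsertion
  post-processing step is implemented.
* ℓ ≥ 2 scoring is exact but O(ball size) per node per step; very large
  networks at high ℓ will be slow (batching trades exactness for speed).
* The message-passing / non-backtracking eigenvalue machinery that
  motivates the CI score is intentionally not implemented; the heuristic
  is the analysis.
* Interolog inference ignores paralog fan-out by design (source-ID
  namespace); organism-side network structure enters only through the
  induced subgraph.
* Uniform resampling is the only null model; degree-preserving rewiring
  nulls are out of scope.
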