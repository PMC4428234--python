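# Methods

## Model and assumptions

The package treats a PPI network as a simple undirected graph on string
labels (gene symbols). All analyses run on the largest connected component;
betweenness and the attack curves are only well defined there, and the
solvers assume every node has at least one neighbor when weights are in
play. Input self-interactions are dropped from the edge set (the protein is
kept), because the self-covering A_ii = 1 term of the domination constraints
is a modeling convention applied uniformly afterwards, not a data feature.
Duplicate and reversed-duplicate edge lines are collapsed silently (a count
is logged): PPI edge lists routinely contain both orientations.

A dominating set must intersect every closed neighborhood
N[i] = {i} ∪ Γ(i). Minimum cardinality (MDS) and minimum weight (CC-MDS) are
both found by the exact mixed-integer solver HiGHS through
`scipy.optimize.milp` (branch-and-bound, zero gap, integrality tolerance
below 1e-6); `proven_optimal` is set only on such results and `solver_id`
records the backend. Decision variables are created in canonical
first-appearance node order and the constraint matrix is emitted
deterministically, so repeated runs return the identical optimum. When
distinct optima share the same weighted objective (nodes with identical
neighborhoods and centralities), the backend's choice stands; on small
graphs the non-uniqueness can be inspected exactly with
`enumerate_minimum_dominating_sets` / `enumerate_weighted_optima`.

## Centrality correction

Degree d_j counts distinct neighbors. Betweenness b_j sums, over unordered
pairs {i,k} with i ≠ j ≠ k, the fraction of geodesics through j, divided by
(n−1)(n−2)/2; endpoints are excluded (Brandes accumulation, via networkx,
whose normalized undirected betweenness uses exactly this normalizer). For
n < 3 the normalizer vanishes and b_j is defined as 0.

The weight ω_j = (d_j·b_j)^(−γ) is undefined when b_j = 0, which happens for
every degree-1 node and many others. The floored value
b'_j = max(b_j, ε) with ε = 0.5/((n−1)(n−2)/2) — half the normalized
contribution of a single geodesic pair — keeps every weight finite while
ranking any zero-betweenness node strictly below any positive-betweenness
node of equal degree. ε is stored in the `WeightVector` and in run manifests
for provenance. At n = 2 the formula for ε degenerates; ε = 0.5 is used
there (weights then depend on degree only). For γ > 0, sorting by ω
ascending is identical to sorting by d·b' descending, so the correction is a
pure preference ordering among candidate sets.

## γ selection

γ is scanned over {0, 0.05, …, 1.00} by default (configurable). Centralities
are γ-independent and computed once per network; one weighted solve per grid
point. The selected γ* is the largest grid value whose solution size equals
the γ = 0 (plain MDS) size. All grid points are checked — the size profile
is usually non-decreasing in γ but this is not assumed. If no positive γ
qualifies, γ* = 0 is returned with a warning rather than guessing, and the
correction degenerates to the plain model. By construction the solution at
γ* is simultaneously a minimum dominating set and weighted-best among
minimum dominating sets; `auto_solve` asserts this invariant on every run.

## Evaluation battery

- **Jaccard overlap** |A∩B|/|A∪B| between driver sets; empty-vs-empty is 1.
- **Attack curves**: the caller orders the driver set by degree descending
  (ties by label); after each single deletion the component count and the
  largest-component fraction of the *original* node count are recorded.
  Deleting an unknown or already-deleted label is an error, not a no-op.
- **Rank-sum comparison** of centrality populations: two-sided Wilcoxon
  rank-sum with mid-ranks for ties. The null distribution is exact when
  n_in·n_out ≤ 400, computed by a subset-sum dynamic program over the
  (doubled) pooled mid-ranks — mathematically identical to enumerating all
  C(N, n_in) group assignments, but feasible at balanced sizes where literal
  enumeration is not. Larger samples use the tie-corrected normal
  approximation with continuity correction (scipy's Mann–Whitney U, an
  equivalent test). Sidedness is fixed at two-sided; the direction is
  reported as the median difference.
- **Gene-list enrichment**: one-sided (over-representation) Fisher's exact
  test; the p-value is the hypergeometric upper tail P(X ≥ k) of the overlap
  between the driver set and the annotated set, both restricted to the
  universe. The universe is the network's largest-component node set;
  annotations outside it are discarded before testing (driver sets are
  network-restricted by construction, so any other universe would inflate
  significance). The sample odds ratio gets a 0.5 (Haldane) continuity
  correction when a table cell is zero.
- **Per-term enrichment** applies the same test per annotation term with
  Bonferroni correction; the factor m counts only terms with at least one
  annotated member inside the universe, not the full ontology. Significance
  is declared at corrected p < α (default 0.01).
- **Membership counts** report how many terms (complexes, GO annotations)
  contain each protein; unannotated proteins count 0.

## Synthetic data

`make_figure1_fixture` builds a deterministic 10-node, 15-edge two-hub
graph whose minimum dominating sets are exactly {1,6}, {5,10}, {1,10},
{5,6}: nodes 1 and 5 are the only common closed neighbors of nodes 2–4, and
6 and 10 of nodes 7–9, so every 2-set optimum pairs one hub-side coverer
with one from the other side. Nodes 5 and 6 maximize d·b, so any corrected
solve with γ > 0 picks {5,6}. These claims are verified against the
enumeration oracle at test time rather than trusted.

`random_network` produces seeded Erdős–Rényi ("uniform-random") or
Barabási–Albert ("preferential-attachment") graphs reduced to their largest
component; identical parameters and seed give identical edge sets. The
preferential-attachment model reproduces the heavy-tailed degree
distribution of PPI networks but none of their biological structure (no
date/party hub distinction, no complex clique structure, no degree
correlations), so passing tests demonstrate algorithmic correctness, not
biological fidelity. `planted_annotation` emulates gene lists (essential,
aging, disease genes) by annotating target nodes with probability
`inside_rate` and the rest with `outside_rate`; equal rates give a null list
for type-I checks.

## Problem sizes and numerical choices

The test suite exercises the exact solvers against brute-force enumeration
on 200 seeded connected graphs with 4–12 nodes, the enrichment p-values
against direct hypergeometric tail summation exhaustively for universes up
to 14 with a systematic grid of tables up to 60, the exact rank-sum branch
against literal permutation enumeration for group sizes up to 6, and the
planted-enrichment simulation at 100 seeds (power, inside/outside rates
0.5/0.1, 50-node target in a 500-node scale-free graph) and 1,000 seeds
(type-I, equal rates). The acceptance script repeats these at 100 graphs
and the same simulation sizes; the γ-stability summary uses a 300-node
scale-free graph with γ up to 0.5. These sizes keep each suite in the
seconds-to-a-minute range while leaving every check exact or
well-resolved statistically.

Floating-point ties in the weighted enumeration oracle are resolved at
1e-12; weighted-objective agreement between solver and oracle is asserted at
1e-9. Exact rank-sum tail membership uses a 1e-9 slack so mid-rank
arithmetic cannot drop boundary assignments.

## Known limitations

- Betweenness is computed exactly; no sampling approximation is provided, so
  very large networks pay O(nm) per scan (once, since centralities are
  reused across the γ grid).
- The critical/intermittent/redundant node classification (which needs n
  re-solves), 2-domination variants, bipartite extensions, graphlet-degree
  heuristics, and GO true-path propagation are out of scope.
- Gene-identifier normalization is not performed: node identity is the
  whitespace-trimmed label, and annotation files must already use the same
  symbols as the network.
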