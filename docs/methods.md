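# Methods

## The model

`orcci` detects communities in undirected, unweighted simple graphs — the
setting of binary protein–protein interaction networks — from the coarse
geometry of the graph. For an edge (x, y), the Ollivier-Ricci curvature is

    kappa(x, y) = 1 − W1(m_x, m_y) / d(x, y),

where m_x places a probability mass of (1 − alpha)/deg(x) on each neighbor of
x (a *laziness* fraction alpha of the mass may stay on x; the default is
alpha = 0, all mass on the neighbors), W1 is the Wasserstein-1 (earth mover's)
distance under hop-distance ground costs, and d(x, y) = 1 for an existing
edge of an unweighted graph. Edges inside densely interlinked neighborhoods
overlap heavily and have positive curvature; bridges between such
neighborhoods force mass across long detours and have negative curvature.

Community detection is a Girvan–Newman-style removal hierarchy driven by
curvature: repeatedly delete the unprotected edge with the most negative
curvature (strictly below a configurable threshold, default 0), refresh the
curvature of the edges the deletion can influence, and record the connected
components and their Newman modularity

    Q = sum_c [ e_c/m − (d_c/(2m))^2 ]

after every deletion, with e_c, d_c and m always measured on the *original*
input graph (evaluating Q on the residual graph would trivially favor late,
shattered partitions). Two hierarchy levels are reported: the **final**
partition once no removable negative edge remains, and the
**maximum-modularity (MM)** partition at the step where Q peaks; ties in Q
resolve to the earliest (coarsest) step, since the MM level is by
construction an intermediate, merged view.

**Side information.** A-priori labels (e.g. phytohormone pathway membership)
on a node subset S act as a hard constraint: an edge whose endpoints share at
least one label is never removed, regardless of curvature. Protection is
absolute and deterministic; a soft/probabilistic weighting is out of scope.
If every node carries its true community label, every intra-community edge is
protected, so each community's induced connected subgraph survives to the
final partition by construction.

## Ground metric during the loop: original vs residual

Whether the hop distances feeding W1 should be re-measured on the thinned
residual graph after each removal, or kept fixed at the input graph's metric,
is a genuinely open design point — the removal loop is usually stated without
fixing it. Both are implemented (`DetectionConfig.distance_mode`); the
default is `original`:

* with **original** distances, a deleted bridge still provides its 1-hop
  ground cost to other edges' transport problems; neighborhood mass evolves
  but the metric does not. Cohesive blocks stop producing negative edges soon
  after their bridges are gone.
* with **residual** distances, each deletion lengthens detours, which pushes
  further edges negative and continues splitting inside communities; the
  final partition becomes markedly finer. On a 4×50-block benchmark
  (p_in = 0.25, p_out = 0.01) the final-partition NMI is ≈ 0.93–0.99 under
  the original metric versus ≈ 0.65–0.79 under the residual one, while the
  MM partition is a perfect 1.0 under both.

The residual mode is retained as a sensitivity flag; everything else
(protection, modularity tracking, tie-breaking) is identical between modes.

## Exact transport solves

Each curvature evaluation is one small transportation problem between the two
endpoint neighborhoods. Because every ground distance between support nodes
of an existing edge is at most 3 hops (neighbor–endpoint–endpoint–neighbor),
costs are integers in {0, 1, 2, 3}, and the neighbor masses are exact
rationals (denominator lcm of the degrees and the laziness denominator). The
default backend scales masses to integers and solves the min-cost flow by
successive shortest paths with potentials — exact integer arithmetic, no
tolerance; results are floats only at the final division. A scipy HiGHS LP
backend covers non-rational masses and serves as a verification route; the
test suite additionally checks both against an exhaustive Fraction-arithmetic
enumeration over transportation-polytope vertices on all connected graphs
with ≤ 6 nodes, to 1e-9.

Numerical/tie-break conventions, all deterministic:

* edges are stored with endpoints in lexicographic order; among equally most
  negative edges the lexicographically smallest is removed first;
* component ids are the lexicographically smallest member node;
* an isolated-edge component gives m_x = delta_y, m_y = delta_x, W1 = 1,
  kappa = 0 — flat, never removed at the default threshold;
* curvature of a degree-0 node's (nonexistent) neighborhood is an error, and
  isolated nodes simply become singleton communities;
* laziness is accepted in [0, 1); as alpha → 1 both distributions concentrate
  on the two distinct endpoints, so W1 → d(x, y) = 1 and kappa → 0 for every
  edge (the flat limit).

## Incremental recomputation

After deleting (x, y), only edges with an endpoint within 3 hops of x or y
(pre-removal distances) can change curvature: any transport-relevant shortest
path of a surviving edge lies within that radius. The engine maintains exact
walk-count matrices A² and A³ with O(n·deg) incremental integer updates per
deletion, reads the hop-distance classes {1, 2, 3, >3} off them, and re-solves
an edge only when its endpoint neighborhoods or cost submatrix actually
changed — which makes the incremental path *bit-identical* to full
recomputation (verified on 50 seeded random graphs, and exposed as
`full_recompute=True` for independent checking). Under the frozen (original)
metric the changed set shrinks further to the edges incident to the deleted
endpoints.

## The synthetic benchmark

`generate_sbm` plants communities with a stochastic block model: every
unordered node pair is an independent Bernoulli draw, p_in within a block and
p_out across. The default benchmark is 1000 nodes in 10 blocks of sizes
[150, 125, 125, 110, 100, 100, 90, 75, 75, 50]. The edge probabilities are
**not** determined by that configuration; the defaults p_in = 0.10,
p_out = 0.005 are this package's choice of a detectable but hard assortative
regime (expected intra-degree ≈ 10 against inter-degree ≈ 4.5, final-partition
NMI ≈ 0.66 at 60% observability), and any quantitative claim should state
them explicitly.

Partial observability takes the induced subgraph on a uniform sample of
round(f·n) nodes (round-half-up, so percentage grids are exact); side
information labels a uniform sample of round(f·n_obs) observed nodes with
their true block id; corruption replaces the labels of round(f·|S|) labeled
nodes by a uniformly drawn *wrong* block id. Graph generation, observation,
labeling and corruption consume independent sub-streams spawned from one
instance seed, so sweeping one grid axis leaves the other draws unchanged.
Truth labels of communities fragmented by observation are kept, not
re-derived per component — low observability therefore caps achievable NMI by
breaking communities into islands before detection starts.

What the generator does *not* emulate: degree heterogeneity and hubs
(no degree correction), multi-label or hierarchical annotations, correlated
false edges, and any metadata-dependent edge process. Passing the benchmark
therefore shows recovery of clean planted assortative structure under
uniform node dropout — not performance on scale-free interactomes.

## Evaluation

NMI uses natural-log entropies with the arithmetic normalization
2I/(H_p + H_q) (the common community-detection convention; `max` and
`geometric` are options), is computed over observed nodes only, and is
defined as 1 when both partitions are a single community. The
information-retrieval metrics default to pairwise co-membership counting
(TP = pairs together in both partitions, etc.); a per-node majority-label
variant is available behind `scheme="node_majority"` since either reading is
defensible — both are reported by the CLI-facing code, neither is privileged.
Pathway-protein ratio assigns each community the plurality label among its
annotated members (lexicographic tie-break) and divides that label's carrier
count by the full community size; unannotated communities are excluded from
the mean. Overlap/variation reports match each baseline community B to the
detected community D maximizing |D∩B| (ties to the smallest id) and report
|D∩B|/|B| and |D\B|/|B|, plus the count, union size and summed size of *all*
detected communities intersecting B (union and sum are both given because
either aggregate is a reasonable reading); matches with |D| > 5|B| are
flagged untestable and excluded from aggregate means.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run, as this package's standard
verification scale: the full ≤ 6-node connected-graph atlas against the
enumeration oracle; 50 random graphs of ≤ 40 nodes for incremental/full
equivalence; 20 seeds of the 4×50-block recovery benchmark; the 1000-node
default benchmark at 60% observability for the side-information sweep
(25 paired seeds in the test, 6 in the acceptance script); and 4×30-block
full-knowledge runs. These sizes keep a complete run in the tens of minutes
on one CPU while exercising every code path at the documented defaults.

## Known limitations

* The removal loop is O(E) transport solves per full refresh; graphs beyond
  ~10^4 edges need the approximate-transport speedups that are explicitly out
  of scope here.
* Exactly one edge is removed per iteration; simultaneous removal of tied
  edges would yield a different (also defensible) hierarchy.
* Side-information protection is hard; a single wrong shared label
  permanently protects a spurious edge (the corruption benchmark quantifies
  the resulting degradation).
* Weighted or directed graphs, overlapping communities, and degree-corrected
  benchmarks are not supported.
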