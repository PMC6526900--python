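# Methods

This note documents the model, the numerical and design choices, and the
limits of what the test suite demonstrates.

## Problem statement and scope

Given an undirected simple network G (vertices are proteins/genes; edges
are interactions), find all connected patterns H with 3 ≤ |V(H)| ≤ K whose
edge-disjoint occurrence count in G is (a) at least a frequency threshold F
and (b) significantly larger than in an ensemble of degree-preserving
randomized networks. Occurrence semantics are **non-induced**: an
occurrence is an injective vertex mapping preserving all pattern edges;
extra edges among the image vertices are allowed. Directed, weighted and
labeled networks, induced counting, and sampling-based approximate censuses
are out of scope.

## Graph model and input handling

Vertices are dense 0-based integers; external identifiers live in a side
table and patterns are matched purely topologically. SIF input
(`source relation target [target2 ...]`) and two-column edge lists are
supported; duplicate edges and self-loops are silently dropped, single-token
SIF lines declare isolated vertices. Isolated vertices are retained — they
count toward the network order n, and therefore toward the default
frequency threshold F = ⌈0.05·n⌉ — but can never appear in an embedding.
No other pre-processing (largest component extraction, interaction-type
collapsing) is applied.

## Canonical labeling

Pattern identity is decided by a canonical form: isomorphism testing
reduces to string equality, and the canonical vertex order is the frame to
which all embeddings are aligned. The canonical order is found by placing
vertices one position at a time and minimising, lexicographically, the
sequence of adjacency bits between each newly placed vertex and the prefix.
Because every order contributes the same number of bits per position, greedy
per-position minimisation with branching on ties is an exact lexicographic
minimisation. Two refinements keep the search small:

- **Twin collapsing.** Tied candidates whose adjacency differs at most in
  their mutual bit are interchangeable by an automorphism; only one is
  branched on. This bounds the search on cliques, stars and complete
  bipartite patterns, which are otherwise worst cases.
- **Prefix pruning.** A branch is cut as soon as its bit sequence exceeds
  the best known one at the same position.

The emitted `canon_string` is the row-major upper triangle of the
canonically ordered adjacency matrix (k(k−1)/2 characters); the
accompanying permutation maps input positions to canonical positions.
Ties among optimal orders are broken by first-found under ascending vertex
id, so the permutation is deterministic. Canonical forms of identically
labeled graphs are cached process-wide (the same candidate matrices recur
when trees are rebuilt per network). Supported pattern sizes are 2–15;
patterns are required to be connected. Mean cost is ≈0.3 ms for an
8-vertex pattern, which is what makes full size-8 tree construction
(≈150k candidate canonicalisations) run in tens of seconds.

Correctness is cross-checked in the tests against (a) an all-bijections
isomorphism search and (b) igraph's BLISS-based isomorphism test, and by
the known counts of non-isomorphic connected graphs (2, 6, 21, 112, 853
for k = 3..7).

## Expansion tree

The root is the 3-vertex path. Vertex-addition levels extend each pattern
by one pendant vertex per attachment point; once patterns reach the target
size k, edge-addition levels insert one absent edge per level until K_k.
Child generation is deterministic: attachment vertices in canonical index
order, absent pairs row-major on the upper triangle.

Deduplication policy: a candidate isomorphic to an existing child of the
*same* parent adds a parent link (attachment element + permutation) to that
child; a candidate isomorphic to any other node in the registry is skipped
without storing a link. Consequently every node's parent links point to a
single parent, and the census can drive each child from that parent's
aggregated embedding list without double-expansion. This skip-without-link
rule is implemented as specified even though it means cross-parent arrival
orders influence which parent a shared pattern hangs from in a lazily grown
tree; completeness of the census is unaffected (see below).

Built exhaustively, the tree's node count is (non-isomorphic trees on
3..k−1 vertices) + (connected graphs on k vertices): 2, 7, 24, 118, 865,
11140 for k = 3..8. These counts are the acceptance surface of the tree
builder. One guard in the recursion was stated ambiguously in the design
material (a vertex count compared against k(k−1)/2); it is implemented as
"recurse until the pattern's *edge* count reaches k(k−1)/2", i.e. edge
addition continues until the complete graph, which is the only reading
consistent with the tree's definition.

## Census

Root occurrences are enumerated as ⟨v, w, u⟩ with center u and neighbor
pair v < w — one tuple per occurrence by construction. A vertex-addition
child's occurrences are produced by extending each parent embedding through
every neighbor of the image of the stored attachment vertex (skipping
vertices already used); an edge-addition child's by keeping the parent
embeddings whose image contains the closing edge. The stored permutation
then re-aligns each tuple to the child's canonical order. No canonical form
is computed during these phases — an instrumented counter in the tests
verifies zero canonicalisations on a pre-built tree.

Two derivation orders can reach the same occurrence (automorphic
re-discoveries), so each node's list is deduplicated on the image edge set,
one representative kept (first found, deterministic). Frequencies therefore
count occurrences, not traversals.

Completeness: every occurrence of a child pattern contains an occurrence of
its (single) tree parent, and the stored links cover all attachment orbits
of that parent, so propagation from the parent's full occurrence list
yields all child occurrences. The default pipeline, however, propagates the
parent's *edge-disjoint* subset, as the original pattern-growth design
prescribes; this can undercount descendants relative to full propagation.
Both modes are available (`propagate full|disjoint`, default `disjoint`);
oracle-equivalence tests run under `full`, where the census provably
matches independent subgraph matching (verified on 50 random graphs for all
patterns up to size 5).

## F2 frequency and MIS

The conflict graph joins two occurrences when their image edge sets
intersect (vertex sharing alone is no conflict). The F2 count is the size
of an independent set: exact branch-and-bound (pivot on the max-degree
item, greedy absorption of degree ≤ 1 items, popcount bound) up to 25
items, and above that a deterministic greedy that repeatedly takes the item
with the fewest remaining conflicts (ties by lexicographic vertex list,
then index). The 25-item cutoff is configurable; it keeps exactness where
it is cheap and guarantees determinism everywhere. The greedy result is
always a *maximal* independent set, hence a valid F2 lower bound; downward
closure is asserted in the tests only where both parent and child were
solved exactly, since a heuristic child count may not be comparable.

Thresholding: a pattern is frequent when F2 ≥ F. The pseudo-code
formulation of the threshold uses a strict inequality while the prose reads
"exceeds the threshold"; the inclusive reading is the default here so that
a pattern sitting exactly at 5% of the network order counts, and
`--strict-threshold` restores the literal strict comparison.

## Null model and significance

Randomized networks come from edge switching: pick two distinct edges
uniformly, orient each uniformly at random, and swap endpoints
((a,b),(c,d) → (a,d),(c,b)) unless the four endpoints are not distinct or a
replacement edge already exists — rejected proposals are simply skipped.
Attempts (not successes) are counted; the default is q = 10 attempts per
edge, a standard mixing allowance, and the mixing sanity test checks that a
50-vertex random graph retains well under 90% of its original edges.
Connectivity of randomized networks is deliberately not enforced. Every
replicate's seed derives deterministically from the master seed.

For each size k = 3..K, the census runs on the real network and on N
randomizations (fresh ensemble per k, seeds derived from the master seed
and k). A pattern never reached in a null census contributes frequency 0
for that replicate; note this slightly understates null frequencies of
patterns pruned below F there, which is inherent to running the same
pruned search on the nulls. z-scores use the sample standard deviation
(n−1); with zero spread, z is +∞ above the mean, 0 at it, −∞ below.
Selection uses z ≥ Δ only; the empirical p-value
(1 + #{f_null ≥ f_real})/(N + 1) is reported for information. Results are
reported per size, sorted by (k, descending z); no multiple-testing
correction is applied. The expansion tree is rebuilt per network and per
size — its shape is data-dependent — while canonical forms are cached
process-wide.

## Synthetic data

The test surface is fully synthetic:

- `erdos_renyi(n, p, seed)` — seeded G(n, p).
- `planted_motif_graph(pattern, copies, noise_n, noise_p, seed)` — `copies`
  vertex-disjoint pattern instances (hence F2 ≥ copies by construction),
  an ER noise block, and one bridge per planted copy to a *distinct* noise
  vertex. Distinct bridge endpoints prevent bridges from completing new
  cliques across blocks, so with `noise_p = 0` the planted F2 is exact.
  The recovery fixture is 30 planted K4s with a 200-vertex, p = 0.01 noise
  block (320 vertices, ≈430 edges): dense enough that tree-shaped patterns
  are abundant in both real and null networks (true negatives) while
  cliques exist only where planted.
- `all_small_graphs(k)` — every connected graph on k ≤ 7 vertices, once per
  isomorphism class, by brute-force edge-subset enumeration (restricted to
  labelings with non-increasing degree vectors, which every class
  contains) with canonical dedup. This generator shares no code path with
  the expansion tree and is the oracle for its completeness.

What the synthetic fixtures do *not* emulate: the heavy-tailed degree
distributions, degree–degree correlations and clustering of real PPI
networks, measurement noise, or interaction confidence scores. Passing the
planted-recovery test shows the pipeline recovers a strong, clean signal;
it does not calibrate sensitivity or false-discovery behaviour on real
interactomes.

## Operating parameters

| parameter | default | meaning |
|---|---|---|
| K (`--max-size`) | 5 | largest motif size searched (supported 3–15; sizes beyond ~10 are practical only on sparse networks thanks to pruning) |
| F (`--freq`) | 0.05 | frequency threshold; < 1 means fraction of the vertex count (ceiling), ≥ 1 an absolute F2 count |
| Δ (`--z-threshold`) | 2.0 | uniqueness threshold on the z-score |
| N (`--null-count`) | 100 | randomized networks per size |
| q (`--swaps-per-edge`) | 10 | switching attempts per edge |
| `--propagate` | disjoint | grow children from the edge-disjoint set (`disjoint`) or the full occurrence list (`full`) |
| MIS exactness cutoff | 25 | largest conflict graph solved exactly |

## Problem sizes used in the checks

The acceptance script builds the full static trees for k = 4..8 (up to
11140 nodes) and the tree levels to size 10 (199 trees); the test suite
exercises the census against brute-force matching on random graphs with at
most 12 vertices and patterns up to size 5, the null model on 100
randomizations, and planted-motif recovery on five seeds of the 320-vertex
fixture with N = 20 nulls. These sizes were chosen so each check is decisive
for the property it tests while the whole suite stays interactive.

## Known limitations

- F2 counts above the exactness cutoff are greedy lower bounds, as in any
  practical MIS-based frequency; this affects tightness, not validity.
- Disjoint propagation (the default, faithful to the pattern-growth
  design) can undercount descendant patterns relative to full propagation;
  use `--propagate full` for sensitivity analysis on small networks.
- Null frequencies of patterns pruned in a null census are recorded as 0,
  biasing z upward for borderline patterns.
- The static tree is exponential in k (≈1.2 × 10^7 nodes at k = 10); only
  the dynamic, pruned form is meant for k > 8.
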