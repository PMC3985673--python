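# Methods

## The module-map model

The input is a pair of networks H = (V, E_H, W_H) and G = (V, E_G, W_G)
on the same vertex set; on loading, both are restricted to the
intersection of their node sets (dropped counts are logged). A module
map F = (M, L) consists of pairwise-disjoint modules M₁, …, Mₚ ⊆ V and
links L between module pairs; in a finalized map every module
participates in at least one link and every module has at least
`min_module_size` nodes.

For unweighted networks the signed-weight convention is +1 for an edge
and −1 for a non-edge; non-edges are never materialised, weights are
derived from edge-set membership on demand. Weighted networks carry a
real weight for every pair (pairs missing from an input file default
to −1, the non-edge value). The global score is the sum of signed
H-weights within modules plus the sum of signed G-weights across
linked pairs, so dense modules and dense links raise the score and
sparse ones lower it. The convention implies an implicit density
threshold of ½: a structure scores positively only if more than half
its pairs are edges. With different non-edge weights the same
machinery would favour sparser modules; only the ±1 convention is
implemented.

### Link significance

A candidate pair (U, V) is tested node-wise. In the hypergeometric
variant (the default, used for both unweighted and weighted inputs;
weighted G is binarized at weight > 0 to form G′), the statistic for
x ∈ U is the number k of G′-edges from x into V, referred to the
hypergeometric distribution with population N − 1 (all nodes except x
itself — membership of x's own module is not excluded, as there is no
ground to do so), successes deg(x), and draws |V|. The per-node
p-values of all nodes of U and V are combined with Fisher's method.
In the rank-based variant, the weights from x into V are compared with
the weights from x to all other nodes by a one-sided Wilcoxon rank-sum
test and combined with Stouffer's method. All tests are one-sided
(enrichment only): the method detects links, not depletions.

Thresholds: α = 0.005 declares a link, β = 0.2 declares an anti-link.
Anti-links are sticky: once a pair tests at p ≥ β it is cached and the
status is inherited by any merged superset pair without re-testing.
This inheritance is what keeps the improver's candidate space near
linear in practice. A pair with no cross G′-edge at all evaluates to
p = 1 without touching scipy; such evaluations still increment the
test counter, since the Bonferroni option is defined over "all tests
performed".

## Initiators

* **mbc-dicer** (default): enumerate all maximal non-induced bicliques
  of G′ with both sides ≥ the minimum module size; split each side
  into connected components of its induced positive-H subgraph (a
  maximal biclique may span several modules linked to the same
  partner, and a module must be H-connected); clean every cross pair
  of components; rank cleaned pairs by combined internal H score; and
  accept greedily with first-come node claiming. A later pair keeps
  the unclaimed remainder of a side; a side survives only at
  min-size. Seed links join pairs whose two sides both survive.
* **dicer-k**: iterate over G′-edges (heaviest first, ties
  lexicographic); each unclaimed edge seeds a pair of singleton sides
  grown greedily by the node with the best positive gain (own-side
  H-weight plus cross G-weight). The grown pair is cleaned, and
  accepted if both sides have ≥ k nodes and the pair qualifies as
  linked under the local rule — positive summed cross G-weight.
  Accepted nodes leave the pool, so a module shared by two links
  seeds only once.
* **hclust**: average-linkage agglomerative clustering of H at
  distance w_max − w, tree cut largest-first into clusters within
  [min_size, max_size]; returns unlinked sets.
* **greedy**: modules grown around the heaviest unused H-edges by
  best positive marginal internal score.

### Cleaning

A side is cleaned by repeatedly removing the node whose summed
H-weight to the rest of its own side is lowest, while that sum is
≤ 0; a one-node remainder is discarded (it has no positive tie). Each
side only shrinks, so cleaning terminates within |side| steps. The
original cleaning procedure of the DICER family is not published in
detail; this fixpoint rule is this package's own concrete choice and
is deliberately the same criterion used during dicer-k growth
acceptance.

### Maximal biclique enumeration

Maximal non-induced bicliques correspond to the closed sets of the
Galois operator f(S) = ∩_{s∈S} N(s): every maximal biclique is a pair
(A, f(A)) with A = f(f(A)). Closed sets are enumerated exactly once by
prefix-preserving closure extension; the side-size bound prunes
monotonically (f only shrinks along a branch), and each biclique is
emitted from its lexicographically smaller side. The kernel runs on
packed 64-bit adjacency bitsets under numba. Two caps guard against
exponential blowup on dense graphs: `max_results` (default 10⁶) on
emitted bicliques and `max_explored` (default 20×) on visited closed
sets; hitting either flags truncation in the returned metadata and
logs a warning. Exploration is ordered low node-index first so a
truncated run still covers a deterministic prefix of the graph.

## Improvers

The improver state holds the seed sets plus every unassigned node as a
singleton, cross-set H-weights/G-weights/G′-edge counts (maintained
additively under merges, so gains and scores are exact and cheap), and
the link-status cache over all live pairs (filled once at
initialisation).

**Global improver.** Merge candidates are module–module and
module–singleton pairs sharing at least one H-edge or G′-edge;
singleton–singleton merges are excluded to bound the candidate space
(a consequence: a planted module entirely absent from the seeds cannot
be rebuilt from loose genes — acceptable because the default initiator
always seeds every module that survives noise). The gain of merging
(A, B) is computed exactly: cross H-weight of A×B, plus the link
weights of the merged set Y (links re-determined against every live
set not anti-linked to A or B; anti-links inherited silently), minus
the link weights currently held by A and B. Per iteration either the
single best positive proposal is applied, or — batch mode, the
default — a maximal family of pairwise-disjoint positive proposals in
descending gain order, each re-validated against the current state
immediately before application. Re-validation is what guarantees the
realised global score never decreases even though earlier merges in
the batch can invalidate a pre-computed gain; the score log asserts
monotonicity at run time. Equal gains break ties by smallest member
node id. Termination: every merge reduces the set count by one, so at
most n − 1 merges occur.

**Local improver.** Operates only on the initiator's links: per pass,
each link side may gain the unassigned node with the best positive
summed contribution (H to its side, G across the link), and two links
sharing a module merge their non-shared modules when the cross
H-weight between them is positive (cross G-weight to the shared module
is additive and cancels). Runs to a fixpoint. It cannot create
modules absent from the initial solution. The final state re-tests
link p-values on the final memberships.

**Finalization.** Sets below the minimum size are dropped; cached
linked pairs are accepted at p ≤ α (or p ≤ 0.05 / #tests under the
Bonferroni option, matching the small-network analysis mode); modules
left without any link are dropped, cascading until stable. Link
p-values are never combined from parent sets — they are always the
value tested for the exact final membership (anti-links excepted,
which are only ever used to skip work, never reported).

## Parameters

| parameter | default | meaning |
|---|---|---|
| α (`alpha`) | 0.005 | combined p-value at or below which a pair is linked |
| β (`beta`) | 0.2 | p-value at or above which a pair is permanently anti-linked |
| `min_module_size` | 5 | minimum nodes per module in seeds and the final map (3 suits small dense screens) |
| `dicer_k` | 5 | minimum side size of dicer-k seed pairs |
| `batch_merges` | true | apply disjoint positive merges simultaneously per iteration |
| `correction` | none | `bonferroni` accepts links at 0.05 / #tests instead of α |
| `max_results` / `max_explored` | 10⁶ / 2·10⁷ | biclique enumeration caps (dimensionless counts) |

## Simulator

The generator emulates the benchmark conditions this method is
designed for: an initially empty n-node pair of graphs; modules
planted as H-cliques; the map topology a uniform random labelled tree
(Prüfer construction) whose links are complete bipartite subgraphs in
G; decoy cliques in H and decoy bicliques in G that do not belong to
the map; all planted node sets pairwise disjoint with sizes uniform in
[10, 20]. Defaults are the 500-node setting: six modules, two decoy
cliques, two decoy bicliques. The 1000-node setting uses ten modules
and five decoys; the five-decoy split is not specified anywhere, so
the generator defaults to 3 cliques + 2 bicliques (configurable) —
recovery depends on it only weakly. Noise: unweighted, every pair
flips independently with probability P; weighted, every pair draws
N(+1, σ) if planted and N(−1, σ) otherwise. Node ids are n0001…, with
planted structures on the lowest ids for readable fixtures; all
randomness flows from one integer seed and equal seeds give
bit-identical instances.

What the simulator does *not* emulate: degree-corrected or scale-free
background topology, overlapping modules, weight distributions with
unequal variances, or correlated noise between H and G. Passing
recovery tests therefore demonstrates correctness of the machinery
under the planted model, not performance on real interactomes.

## Evaluation

Recovery is scored with the co-membership **pair Jaccard**: the sets
of unordered node pairs co-assigned to a module, compared between
found and true module collections (1.0 when both pair sets are empty).
The metric is symmetric, invariant to module labels, and robust to
module-count mismatch; the benchmark's original Jaccard variant is not
precisely defined, which is absorbed by the tolerance bands of the
recovery checks. Two real-data procedures are included: a held-out
one-sided rank-sum test comparing mean cross weights of linked vs
unlinked module pairs, and a per-link fold change against the best of
`repeats` random same-size disjoint set pairs, where the link
statistic is the mean positive cross weight (negatives contribute 0,
floored at 10⁻⁶ to avoid division by zero).

## Numerical choices

* p-values are floored at 10⁻³⁰⁰ before log/quantile transforms.
* Wilcoxon: exact enumeration below 20 observations per side when
  tie-free, mid-rank normal approximation otherwise; complete ties
  return p = 1 (no evidence).
* Gains must exceed 10⁻⁹ to count as positive (float safety; gains are
  integers on unweighted inputs).
* Ties everywhere break lexicographically by node id, so every
  pipeline stage is deterministic given its inputs.
* Degenerate inputs: empty maps are valid outputs (warned); a module
  of size ≤ 1 has internal score 0; duplicate input edges collapse
  last-wins with a warning; self-loops are dropped with a warning.

## Problem sizes used by the checks

The test suite and the acceptance script run the noisy benchmark at
the 500-node setting (six modules, 2 + 2 decoys, P = 0.15) with three
replicate seeds, and the improver property checks on twenty 120-node
instances. These sizes were chosen so the whole suite completes
comfortably on a single CPU while leaving every algorithmic path
exercised at realistic density; at the 1000-node setting the biclique
enumeration hits its default work cap (the run is then truncated and
logged, which is the documented behaviour, not an error).

## Known limitations

* The DICER-family internals (cleaning criterion, expansion rule,
  simultaneous-merge scheme) are reconstructed behavioural contracts,
  not ports; the greedy max-gain expansion of `dicer-k` overfits
  background noise on large sparse graphs — it assembles small
  H-dense, G′-cross-dense set pairs out of an Erdős–Rényi background
  whose links are genuinely significant post hoc, which depresses its
  recovery relative to the default initiator and is the main reason
  `mbc-dicer` is the default.
* Directed networks, multigraphs, per-edge confidence models, FDR
  across links, module splitting moves and simulated annealing are out
  of scope.
* The hypergeometric variant treats weighted G through its binarized
  view; weights influence it only through the sign.
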