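# Methods

## The phonological network

A lexicon is a set of phoneme-transcribed word forms. Two words are
neighbors iff their transcriptions are at edit distance exactly 1 under
three operations — substitute, delete, or insert one phoneme. Operations
act on phoneme *tokens* (multi-character symbols are atomic), and
transpositions, stress and syllabification are ignored. The network is
undirected and simple; identical transcriptions (homophones) are distance
0, so homophonous words are distinct nodes with identical neighborhoods
and no mutual edge (an optional merge collapses them; groups are logged).

Construction uses a deletion-variant index: each word is bucketed under
its own sequence and under every single-deletion variant. Any pair at
distance 1 shares a bucket — substitution pairs share a deletion variant,
insertion/deletion pairs share the shorter word's full sequence, and the
empty variant buckets all one-phoneme words together. Candidates are
verified with the exact predicate, so the index affects speed only; tests
assert extensional equality with the O(n²) definition.

## L-spar backbone extraction

Given the network, each edge (u, v) is scored by the Jaccard similarity
of its endpoints' neighborhoods. Two conventions exist and the package
implements both:

* **open** (default): N(u) is the bare adjacency set. An edge in a
  triangle-free region scores exactly 0.
* **closed**: N[u] = N(u) ∪ {u}. Every existing edge then scores > 0,
  because both closed neighborhoods contain {u, v}.

Scores are rank-normalized per node: a node of degree d sorts its incident
edges by descending Jaccard; competition ranks are assigned (ties share
the best rank: 1, 2, 2, 4, …) and reported as (d − r + 1)/d so the
strongest edge(s) score exactly 1. The degree filter retains, for each
node, the edges ranked within the top ⌈d^s⌉; an edge survives if either
endpoint retains it. The ceiling guarantees ⌈d⁰⌉ = 1, so s = 0 keeps each
node's top-ranked edge(s) and s = 1 keeps all. Retention is monotone in s
and, with kept ties at s = 0, no node that had an edge loses all of them.

**Why open is the default.** Under closed neighborhoods ranks are almost
always distinct, so s = 0 nominates ~one edge per node and tree-like
regions lose their bridges — the giant component shatters into fragments
of a few dozen nodes. Under open neighborhoods, all edges of a
triangle-free neighborhood tie at Jaccard 0 and rank 1, so sparse
connective tissue passes through the filter untouched while dense,
triangle-rich regions are aggressively thinned. Only the open convention
produces the behavior backbone extraction is used for on lexicon-shaped
graphs — removing a majority of edges while leaving the set of connected
nodes essentially unchanged — and it is also the convention of igraph's
vertex Jaccard similarity. The closed mode is retained as a flag for
parity testing against other implementations.

Two tie policies are exposed. `keep` (default) retains every edge tied at
the boundary rank; `strict` breaks ties lexicographically by the word-id
pair, retaining exactly ⌈d^s⌉ edges per node, and exists for sensitivity
analysis only — strict nomination at s = 0 cannot explain backbones with
more edges than non-isolated nodes, which is what keep-tie extraction
routinely produces on clique-rich lexicons. Optionally (`umst=True`) the
edges of a maximum-spanning forest under Jaccard weights are united into
the backbone, guaranteeing it connects whatever the original connected;
the default is off.

## Structural metrics

Connected components are ordered by size (descending), ties broken by
smallest word id; the first is the giant component (GC), size-1 components
are hermits/isolates, the rest are islands. Per-word measures: degree;
clustering coefficient C = (edges among neighbors)/(k(k−1)/2), 0 for
k < 2; closeness centrality normalized within the word's own component,
(n_c − 1)/Σ_v dist(w, v), which is 0 for isolates and 1 exactly for a node
adjacent to its entire component. Network summaries report diameter and
mean shortest-path length over all connected ordered pairs across all
components (a `gc_only` flag restricts them to the GC). Path computations
use all-pairs BFS through scipy's sparse csgraph per component — exact,
not approximate; a ~3,000-node GC takes about a second, and the dense
per-component distance matrix is the only sizable allocation (a
6,500-node component needs ~340 MB).

## Communities

Louvain modularity optimization (networkx's seeded implementation) with
resolution 1.0 by default; the seed is recorded in the partition and in
run manifests. Q of the returned assignment is recomputed directly from
Q = Σ_c [e_c/m − (deg_c/2m)²], never taken on faith from the optimizer,
and tests check the formula against an independent pair-by-pair
evaluation and the optimizer against brute-force enumeration on tiny
graphs. When detection runs on a whole network, every isolate is a
singleton community and counts toward the total — the convention that
makes "number of communities" far exceed the number of multi-node
components in lexicon networks. On an edgeless input Q is undefined; the
partition of singletons is returned with Q reported as 0.

## Survivor comparison

Words are grouped as: ORIGINAL_GC (the original network's GC),
BACKBONE_GC (the GC of the retained-edge graph over all nodes), and
GC_NOT_BACKBONE = ORIGINAL_GC ∖ BACKBONE_GC. The first group overlaps the
other two; the three are nevertheless compared as independent samples,
which is the convention of this analysis style. Backbone-GC membership is
not forced inside the original GC; any outside words are counted and
reported. Six variables are compared — familiarity, log₁₀ frequency,
length, degree, C, closeness — with network variables always computed on
the **original** network: membership changes, the measured words do not.

The omnibus test is Welch's heteroscedastic one-way ANOVA: with
w_j = n_j/s_j², F = [Σ w_j(x̄_j − x̄_w)²/(k−1)] / [1 + 2(k−2)Λ/(k²−1)],
Λ = Σ (1 − w_j/Σw)²/(n_j − 1), df₂ = (k²−1)/(3Λ). Post hocs default to
Games–Howell — the pairwise Welch t referred to the studentized range at
the pairwise Welch df — because the groups' variances and sizes are
grossly unequal; pooled-variance Tukey HSD (via scipy) is available where
a literal Tukey correction is wanted. Missing norms are dropped per
variable; a variable absent from any group is skipped with a warning; a
group with fewer than two members is an error, not a NaN row. Frequency
enters as log₁₀(f + 1) by default (an `exclude` policy drops zero counts
instead); p-values are kept at machine precision, with rounding applied
only in formatted reports.

## Synthetic lexicons

The generator draws `n_words` unique phoneme strings: a length from a
distribution over 2–8 phonemes (a discretized Normal(4.06, 0.93), mode 4,
matching typical English word-length norms), then uniform symbols from an
inventory of `inventory_size` tokens. Uniform strings reproduce the
hermit/island/giant-component morphology of real lexicons; they do not
model phonotactics, so their neighborhoods are more homogeneous than a
real language's and community content is meaningless (no /‑et/ families
with shared rimes — only structural analogues).

The default inventory of 15 was calibrated by pilot runs across
inventory sizes {8, 10, 12, 15, 20} at n = 5,000: it is the setting where
the giant component combines a dense short-word core with a sparse
long-word periphery, so that s = 0 extraction strips periphery (the
low-degree, long, low-frequency words) rather than detaching whole
mid-size clusters — the regime real lexicons exhibit and the survivor
analysis presupposes. At that setting ~70% of words are connected and
~75% of edges are removed at s = 0, with the isolate count unchanged.

Norms are explicit stand-ins, not fitted models. Log frequency is
Normal(μ + β·z(degree), σ) truncated at 0, with μ = 0.8 (centring log₁₀
frequency-per-million on typical norms), β = 0.5 and σ = 0.3; β > 0
("degree_coupled", the default) induces the frequency–density coupling
that makes backbone survival frequency-sensitive, while β = 0
("independent") provides the null configuration used to check that
unrelated variables do not separate the groups. Familiarity is
1 + 6·logistic(1.5·z(log f) + ε), ε ~ Normal(0, 0.5), clipped to [1, 7].
Passing tests on these data demonstrate the pipeline's correctness and
the qualitative survivor contrasts; they say nothing about any particular
language's lexicon, which must be supplied as real data.

Everything is seeded: lexicon, norms (seed + 1 for the independent norm
stream), and Louvain. The acceptance script derives all of its randomness
from one `--seed` and re-runs the full analysis at n = 5,000, which takes
well under a minute on one CPU.

## Numerical conventions and edge cases

* Empty transcriptions, duplicate word ids, and ratings outside [1, 7]
  are validation errors at read time, naming the offending row.
* Backbone of an edgeless network: empty retained set, removed fraction
  reported as 0 with a warning.
* Diameter/mean path of a network with no connected pair: reported as 0
  with a degenerate flag and warning.
* Component ordering, edge canonicalization (sorted word-id pairs), and
  strict-tie ordering are all lexicographic, making every output
  independent of node insertion order.
* Welch ANOVA requires each group to have n ≥ 2 and nonzero variance;
  violations raise errors naming the group.

## Known limitations

* Uniform-random lexicons understate clustering relative to real
  languages; backbone GC shrinkage is therefore larger than on real
  lexicons (which shed only a few percent of their GC).
* Exact replication of a published backbone requires matching the exact
  Jaccard convention and tie handling of the original software; both
  switches are exposed (`--mode`, `--ties`) for that purpose.
* The three comparison groups overlap by construction; the Welch tests
  treat them as independent, mirroring the field's practice rather than
  correcting it.
* Louvain is stochastic across seeds; community counts on large GCs are
  stable only to within a few units (Q to within ~0.05).
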