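# phonobackbone

Network-science tooling for the **mental lexicon**: build the phonological
similarity network of a word list, extract its **L-spar backbone**, and ask
which words "survive" the simplification.

In a phonological network, nodes are word forms and an edge joins two words
whose transcriptions differ by the addition, deletion, or substitution of a
single phoneme (so a word's degree is its *phonological neighborhood
density*). Such networks have a characteristic shape: one **giant
component** (GC) holding a large minority of words, many tiny **lexical
islands**, and a majority of unconnected **lexical hermits**. Backbone
extraction removes redundant edges to reveal the network's essential
skeleton — a candidate *kernel lexicon* of structurally important words.
This package is aimed at psycholinguists and cognitive network scientists
who want that analysis as a reproducible pipeline rather than a chain of
GUI tools.

## The method

1. **Graph construction.** For a lexicon of *n* transcriptions, candidate
   neighbor pairs are found with a deletion-variant index (each word keyed
   by itself and by every single-phoneme deletion) and verified against the
   edit-distance-1 definition; the result is provably identical to the
   all-pairs construction.
2. **L-spar backbone.** Every edge (u, v) is scored by the Jaccard
   similarity of its endpoint neighborhoods,
   J(u,v) = |N(u) ∩ N(v)| / |N(u) ∪ N(v)|; scores are rank-normalized per
   node (each node's strongest edge gets 1); and each node of degree *d*
   retains its top ⌈d^s⌉ edges, an edge surviving if **either** endpoint
   retains it. The sparsification exponent s ∈ [0, 1] controls density:
   s = 0 keeps only each node's strongest edge(s) — ties share the best
   rank and are all kept — while s = 1 keeps everything.
3. **Characterization.** Components, degree, clustering coefficient C,
   component-normalized closeness centrality, diameter and mean shortest
   path; Louvain community detection with modularity
   Q = Σ_c [e_c/m − (deg_c/2m)²].
4. **Survivor comparison.** Words in the original GC are split into those
   that remain in the backbone's GC and those that do not; familiarity,
   log₁₀ frequency, length, degree, C and closeness are compared across
   the three groups with Welch's heteroscedastic ANOVA
   (Satterthwaite-adjusted df) and Games–Howell post hocs (Tukey HSD
   available as an option).

A seeded synthetic-lexicon generator (uniform phoneme strings with an
English-like length distribution, plus configurable frequency/familiarity
norms optionally coupled to degree) makes the whole pipeline testable with
no external data.

## Worked example

```bash
phonobackbone simulate --n 2000 --seed 7 --out lexicon.tsv
phonobackbone run-all --lexicon lexicon.tsv --seed 7 --out-dir report
```

prints (abridged):

```
[build] 2000 nodes, 2581 edges
[backbone] retained 1197 / 2581 edges (53.6% removed)
[metrics:original] GC 1074 nodes / 2465 edges; avg degree 2.58 (GC 4.59); diameter 14; avg path 5.58; 747 isolates
[metrics:backbone] GC 717 nodes / 763 edges; avg degree 1.20 (GC 2.13); diameter 69; avg path 25.90; 747 isolates
[communities:original GC] 20 communities, Q = 0.65
[communities:backbone GC] 28 communities, Q = 0.92
[compare] group sizes: {'ORIGINAL_GC': 1074, 'BACKBONE_GC': 717, 'GC_NOT_BACKBONE': 357}
[compare] log_frequency: F(2, 997.60) = 5.31, p = 0.00508
[compare] degree: F(2, 1005.77) = 5.68, p = 0.003523
```

Reading this: more than half the edges were redundant, yet the 747 hermits
stayed 747 — at s = 0 with kept ties no connected word is stranded. The
backbone's giant component is longer-range (diameter 14 → 69) and its
community structure is sharper (Q 0.65 → 0.92 over more communities).
The surviving words are the more frequent, higher-density ones
(significant Welch F for log frequency and degree); familiarity, which
the generator couples to frequency only weakly, does not separate the
groups. The `report/` directory holds the network exports (GraphML),
per-node metrics, partitions, the comparison tables, and a
`manifest.json` recording the input hash and every parameter.

The same commands run on a real lexicon: a UTF-8 TSV/CSV with a header,
one row per word, a `word_id` column and a `transcription` column (either
one symbol per phoneme, `--dialect symbols`, or space-separated tokens,
`--dialect tokens`), plus optional `familiarity` (1–7) and
`frequency_per_million` columns. Column names are configurable with
`--col-*` flags.

Everything is also available as a library:

```python
from phonobackbone import (build_network, extract_backbone, backbone_graph,
                           louvain, summarize)
from phonobackbone.simulate import SyntheticLexiconConfig, generate_lexicon

lex = generate_lexicon(SyntheticLexiconConfig(n_words=2000, seed=7))
G = build_network(lex)
bb = extract_backbone(G, s=0.0)          # BackboneResult
B = backbone_graph(G, bb)
print(summarize(B).gc_nodes, louvain(B, seed=7, gc_only=True).Q)
```

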