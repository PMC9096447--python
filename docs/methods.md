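# Methods

## Annotation model

A document's unit of annotation is the concatenation of its title and
abstract. Tokenization lower-cases the text, maps punctuation to spaces
and removes a small function-word stop-list (content-bearing modifiers
such as "also" or "known" are deliberately kept). Spotting scans the
token sequence left to right and greedily takes the longest anchor-
dictionary match of up to `max_ngram` tokens (default 6); matched spans
never overlap.

Each spotted mention carries candidate senses with their commonness
prior, count(anchor→page)/Σ count(anchor→·). Disambiguation is
collective: for mention *a* and candidate *p*, every other mention *b*
contributes Σ_q rel(q,p)·commonness(b,q) / |candidates(b)|, and the
highest-voted candidate wins. Ties break by higher commonness, then lower
page id, so the choice is total and deterministic; a document with a
single mention falls back to the commonness prior. The annotator is a
local reimplementation of this family of heuristics over the supplied
snapshot; exact fidelity to any hosted annotation service is not claimed.

Annotation quality is ρ = (link probability + coherence)/2, where link
probability is the fraction of the anchor's textual occurrences that are
links (1 when the snapshot carries no occurrence counts) and coherence is
the mean relatedness of the chosen page to the other chosen pages of the
same document (0 when alone — hence a lone, always-linked anchor scores
ρ = 0.5). Two prunes follow, independently switchable: ρ < `rho_threshold`
(default 0.2; 0 disables) and the biological-category filter, which keeps
a page only if some category reaches a designated biology root within
`max_depth` hops up the category graph (default 3; traversal carries a
visited set, so category cycles terminate). Repeated (document, page)
annotations keep the max-ρ instance.

Defaults for `rho_threshold`, `max_ngram` and `max_depth` are package
choices exposed in `AnnotationParams`; no external reference values exist
for them, and the synthetic benchmark is insensitive to `rho_threshold`
below ≈0.4 because link probabilities in the generated snapshot are 0.8.

## Scoring

Relatedness is the Milne–Witten in-link measure with natural logarithms
(the base cancels), clamped to [0,1]; identical pages with in-links score
1, and empty intersections or in-sets score 0.

The projection score uses the degree-tuned hybrid (ProbS/HeatS) form
with exponent λ: s_raw(i,j) = k_e(i)^-(1-λ) k_e(j)^-λ Σ_l a_il a_jl/k_d(l),
symmetrized by arithmetic mean so the graph is undirected. At λ=1 the
unsymmetrized scores conserve resource mass (columns sum to 1), a
property the tests verify against a triple-loop oracle. The
domain-similarity weighting of the original drug–target formulation has
no counterpart over arbitrary encyclopedia entities and is omitted; λ
defaults to 0.5. The computation is sparse — A·diag(1/k_d)·Aᵀ — and never
materializes the full pair space. Projection is corpus-wide over the full
bipartite graph, not per-document batches.

The predicted edge weight is BioTG = s·r. The default prediction
threshold `min_biotg` is 0 (all co-occurring pairs are emitted, ranked);
a single shared document between two singleton entities gives the
reference point s = 0.5.

## Knowledge graph

Nodes are matched by canonical name through the synonym table
(case-insensitive exact matching; fuzzy matching is deliberately
excluded so harmonization is deterministic and idempotent). Node types
are inferred from the origin database of first appearance (e.g. DisGeNET
→ DISEASE, STRING → PROTEIN, miRBase → MIRNA); entities seen only via
annotation stay OTHER. Edges are undirected and unique per (pair, type).

Echo networks rank a seed's neighbours by the best evidence on any edge
to the seed — max(BioTG, STRING score, literature flag) — and n is
restricted to [10, 200]. Shortest paths are unweighted hop counts over
all edge types; among equal-hop paths the lexicographically smallest
node-id sequence is returned (BFS distances from the target plus a
greedy smallest-id walk), making query output reproducible.

Incremental updates filter the new batch to [mindate, maxdate] (undated
documents are excluded), annotate and re-score only the pairs co-occurring
in the batch, over the union of old and new supporting documents of each
pair (a full-corpus re-projection is available behind
`UpdateConfig.global_reprojection`). Supporting-document sets are
unioned, so applying the same delta twice equals applying it once; stale
edges are never removed. The per-document mention map this requires is
persisted as `doc_mentions.json` beside the csv tables.

## Evaluation

Confusion counts are computed over an explicit node universe (all
unordered pairs over the supplied node set); sensitivity and specificity
are percentages truncated — not rounded — to two decimals, so 54/77
reports as 70.12. The universe must be supplied because a specificity
without a defined negative space is meaningless; the CLI defaults to the
union of nodes in the predicted and reference sets.

## Synthetic benchmark

The generator emulates the pipeline's inputs, not their scale: a
120-page snapshot (70 biological pages, category tree of depth ≤ 2 under
one biology root), 50 entity pages, 200 documents, 40 planted relations.
Defaults are the benchmark conditions used by the tests; all randomness
derives from one config seed with sub-generators at fixed offsets.

* Link graph: six hub pages co-cite both members of each planted pair,
  plus two unique citers per entity and background hub-to-hub links, so
  planted-pair relatedness (mean ≈ 0.8) clearly dominates background
  pairs. An entity participating in several planted pairs accumulates
  in-neighbours, so the *fraction* shared with one partner can drop below
  half even though the shared block is always present.
* Anchors: one per entity (alternating one- and two-token texts, so
  spotting exercises longest-match); at `ambiguity_rate` an anchor gains
  a non-biological second sense that *dominates the commonness prior*
  (0.6 vs 0.4), so the benchmark actually measures collective
  disambiguation rather than prior lookup. Link probability is 0.8.
* Corpus: each planted pair is co-mentioned in exactly
  ⌈cooccur_rate·n_docs/n_planted⌉ documents; remaining documents mention
  2–4 random entities; noise injects a non-biological city anchor per
  document with probability `noise_mention_rate`; abstracts are anchor
  phrases joined by filler stop-words (no grammatical realism — the
  annotator removes stop-words anyway); dates are uniform over 2019–2020.

What passing on this generator does **not** show: robustness to real
prose (inflection, nested phrases, hyphenation), realistic anchor
polysemy (two senses here, dozens in a real dump), category-graph depth
and noise, or corpus scale. It does show that spotting, collective
disambiguation, both scores and their product, graph assembly, queries
and incremental updates are each computing the intended quantity, since
every stage is checked against planted ground truth or an independent
oracle.

## Numerical and degenerate-input choices

* Zero-degree documents contribute nothing to the projection (guarded
  division); zero-degree entities cannot occur by construction.
* Degenerate relatedness: denominator log W − log min(|A|,|B|) ≤ 0 (a
  page cited by every page) returns 1.
* All serialization orders rows and keys and formats floats via `repr`,
  so identical inputs give byte-identical `nodes.csv`/`edges.csv`/
  `graph.graphml` — verified end to end.
* Synonym conflicts (one alias claimed by two canonicals) resolve
  first-loaded-wins with a logged warning; unmapped names are kept
  verbatim and tallied.
* Problem sizes in the tests and the acceptance script (50 entities, 200
  documents, ≤30×20 random incidence matrices, ≤100-node path-query
  graphs) are the package's benchmark conditions, chosen so every
  property is exercised at a scale where independent oracles (triple-loop
  projection, breadth-first search, exhaustive planted truth) stay
  practical.

## Known limitations

* The annotator has no candidate shortlist pruning (ε-style) and no
  learned disambiguation; anchor matching is exact after normalization.
* Incremental updates never remove edges, and local re-scoring can
  differ from a full re-projection when document degrees change outside
  the affected pairs' supporting sets (the global mode exists for that).
* Node typing by origin-of-first-appearance is a heuristic; a name
  curated in two databases of different kinds keeps the first type seen.
* Specificity depends entirely on the chosen node universe; comparisons
  across universes are not meaningful.
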