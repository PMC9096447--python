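# biotagme

Literature-derived biological knowledge graphs at desk scale.

Biomedical abstracts mention genes, proteins, diseases, drugs and
pathways together long before curated databases record a relation between
them. `biotagme` turns a corpus of titles and abstracts into a typed,
scored, queryable knowledge graph:

1. **Annotation (wikification).** Each document's title+abstract is
   matched against the anchor dictionary of a Wikipedia-like snapshot.
   Ambiguous anchors are resolved collectively — every other mention in
   the document votes for a candidate sense in proportion to link-based
   semantic relatedness, weighted by the voter's commonness prior
   P(page | anchor). Each annotation is scored with
   ρ = (link probability + coherence)/2 and pruned by ρ and by membership
   in the biological subtree of the category graph.
2. **Prediction.** Annotations form a binary entity × document incidence
   a. The degree-tuned hybrid bipartite projection scores each entity pair

       s_ij = k_i^-(1-λ) · k_j^-λ · Σ_l a_il a_jl / k_l        (λ ∈ [0,1])

   symmetrized as (s_ij + s_ji)/2, where k_i and k_l are entity and
   document degrees. Semantic relatedness r_ij ∈ [0,1] is the
   Milne–Witten in-link measure

       r_ij = 1 − [log max(|A|,|B|) − log|A∩B|] / [log W − log min(|A|,|B|)]

   over the in-link sets A, B of the two pages (W pages total). The
   predicted edge weight is the product **BioTG_ij = s_ij · r_ij**.
3. **Graph construction.** Predicted pairs are merged with curated
   reference databases (harmonized onto one nomenclature through a
   synonym table) into a graph whose node pairs carry up to three typed
   edges: `BIOTAGME` (predicted, with score and supporting documents),
   `STRING` (scored protein association) and `LITERATURE` (curated
   evidence with origins). The graph supports echo-network queries (a
   seed plus its top-n scored neighbours), deterministic minimum-hop
   shortest paths, per-edge provenance records, and incremental updates
   that fold a dated document batch in and re-score affected pairs over
   the union of their supporting documents.

A synthetic-data module generates a self-contained mini-snapshot, corpus
and reference sets with planted relations, so the whole pipeline runs and
is tested without any downloads.

## Worked example

```bash
biotagme simulate --out demo --seed 7
biotagme run --config demo/pipeline.yaml
```

The simulator writes a 120-page snapshot and 200 documents with 40
planted entity relations. The pipeline run prints its stage report:

```json
{
 "annotate": {"annotations": 511},
 "build": {"nodes": 50, "edges": 353},
 "ingest": {"documents": 200, "wiki_pages": 120},
 "integrate": {"literature_edges": 20, "string_edges": 20},
 "predict": {"scored_pairs": 313}
}
```

511 annotations over 200 documents yield 313 co-occurring entity pairs;
merged with the 40 reference edges they form a 50-node graph with 353
typed edges (some pairs carry both a predicted and a curated edge). Of
the 40 top-scoring predicted edges, 37 (92.5%) are planted relations.
The graph directory holds `nodes.csv`, `edges.csv`, `Name_Aliases.csv`
and `graph.graphml`; query it with

```bash
biotagme query echo --graph demo/graph --name "Factor 1" --n 10
biotagme query path --graph demo/graph --src "Factor 1" --dst "BFG2"
```

Evaluation against a reference edge set (`biotagme eval`) reports
confusion counts plus sensitivity 100·tp/(tp+fn) and specificity
100·tn/(tn+fp) over an explicit pair universe.

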