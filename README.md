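# conceptkg

Concept knowledge graphs from annotated document corpora, for comparing
what different stakeholder communities talk about around a medical
condition.

When families discuss a condition such as ADHD or autism spectrum disorder
on web forums, their concerns (sleep, school, medication side effects)
often differ from the topics emphasised in the professional literature.
`conceptkg` takes two corpora of documents that have already been annotated
with canonical biomedical concepts (UMLS-style concept ids with semantic
types and linker confidence scores), builds a ranked "concept map" of each
corpus around the condition, and classifies every shared concept as being
of *similar*, *forum-priority*, or *literature-priority* relevance.

## Method

For each corpus:

1. **Filtering.** Condition synonyms are merged into the canonical
   condition concept, documents not mentioning a condition are dropped,
   mentions with linker score ≤ 0.7 are discarded, each concept keeps its
   first-listed semantic type, concepts outside a 26-type allowlist of
   disorder-relevant semantic types or occurring in fewer than 10 documents
   are removed (both thresholds configurable).
2. **Embedding.** A document-level co-occurrence matrix is built (a
   concept pair counts once per document containing both). With document
   frequencies *d<sub>i</sub>* and pair counts *c<sub>ij</sub>* over *N*
   documents, entries are weighted by positive pointwise mutual
   information,

   PPMI(i,j) = max( ln[ (c<sub>ij</sub>/N) / ((d<sub>i</sub>/N)(d<sub>j</sub>/N)) ], 0 ),

   and the PPMI matrix **M** is factored by truncated SVD,
   **M**<sub>k</sub> = **U**<sub>k</sub>**S**<sub>k</sub>**V**<sub>k</sub><sup>T</sup>
   with k = 300; row *i* of **U**<sub>k</sub>**S**<sub>k</sub> is concept
   *i*'s vector.
3. **Ranking.** Relatedness of concept *i* to the condition *c* is the
   cosine **C**<sub>i</sub>·**C**<sub>c</sub> / (‖**C**<sub>i</sub>‖‖**C**<sub>c</sub>‖).
   Within each semantic type the top 25 concepts are kept.
4. **Graph.** A property graph: the condition node (frequency 1), one node
   per semantic type (`isRelatedTo` edge to the condition, frequency =
   mean over its selected concepts), one node per selected concept (`isA`
   edge to its type, weighted by relatedness; node frequency = proportion
   of condition documents the concept co-occurs in).

Two corpora are then compared: their graphs are merged with one `sameAs`
edge per concept selected in both, and for every concept scored in both
corpora the score difference diff = FR − PR (forum minus literature
relatedness) is computed. With µ and σ the mean and population standard
deviation of the diffs, a concept is *forum-priority* if diff > µ + 2σ,
*literature-priority* if diff < µ − 2σ, and *similar* otherwise.

A synthetic-corpus generator with planted latent topics
(`conceptkg.synthetic`) provides ground-truth relatedness orderings, so the
whole pipeline is testable without scraped data or licensed vocabularies.

## Worked example

Generate two synthetic corpora (each planted with two topics, one of which
carries the condition `C_COND`), then compare them:

```bash
conceptkg generate --n-docs 600 --seed 11 --source forum  --out forum.jsonl
conceptkg generate --n-docs 600 --seed 12 --source pubmed --out pubmed.jsonl
conceptkg compare --config config.yaml
```

with `config.yaml`:

```yaml
corpora:
  forum: forum.jsonl
  pubmed: pubmed.jsonl
condition_id: C_COND
filter:
  min_doc_count: 1
  condition_ids: [C_COND, C_COND2]
k: 300
top_k: 25
seed: 11
out_dir: run
```

The compare command prints the comparison summary:

```json
{
  "category_counts": {
    "forum_priority": 0,
    "pubmed_priority": 2,
    "similar": 13
  },
  "mu": -0.000692577374552681,
  "sigma": 0.002544549030382052,
  "n_compared": 15,
  "same_as_edges": 15,
  ...
}
```

Fifteen concepts were selected in both corpora and linked by `sameAs`
edges; thirteen fall within µ ± 2σ of the score-difference distribution
(similar priority in both corpora) and two sit below µ − 2σ (relatively
more related to the condition in the `pubmed` corpus at these seeds). Per
corpus, `run/<source>/selection.tsv` holds the ranked concepts, e.g.

```
semantic_type        rank  concept_id  name    relatedness         frequency
finding              1     C_A03       C A03   0.847067107859056   0.782051282051282
finding              2     C_B06       C B06   2.31e-16            0.0299...
individual behavior  1     C_A05       C A05   0.8568971256132522  0.8119...
```

— planted topic-mates of the condition (`C_A*`) score ≈ 0.85 while
unrelated concepts (`C_B*`) score ≈ 0, which is the ground-truth ordering
the generator planted. `run/merged_kg.graphml` holds the linked graph
(check it with `conceptkg validate run/merged_kg.graphml`), and each
source directory contains the vocabulary, relatedness table, GraphML and
node/edge CSV exports, and a `manifest.json` with per-stage counts.

## Corpus format

One JSON document per line:

```json
{"doc_id": "d0", "source": "forum",
 "mentions": [{"concept_id": "C0003467", "name": "Anxiety",
               "semantic_types": ["finding"], "score": 0.92}]}
```

The packaged 26-type semantic-type allowlist is in
`src/conceptkg/data/semantic_types.txt` and can be overridden via
`filter.allowed_semantic_types` in the config.
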