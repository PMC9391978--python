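# Methods

## Model and assumptions

`conceptkg` operates on *annotated* documents: each document is a bag of
canonical concept mentions (id, preferred name, ordered semantic-type
list, linker confidence in [0, 1]). Free text, entity linking, and corpus
collection are outside the package; a small dictionary annotator
(`synthetic.annotate_with_dictionary`) exists only to turn hand-written
strings into fixtures.

The core assumption is distributional: concepts that occur in the same
documents are topically related. The context unit is the whole document
(global context), which favours topical association over syntactic
similarity — appropriate because the goal is a map of *concerns around a
condition*, not a thesaurus. Presence is binary per document; repeated
mentions of a concept in one document count once, so verbose documents do
not inflate co-occurrence.

## Filtering

Mention level: a mention survives if its linker score is **strictly
greater** than `score_cutoff` (default 0.7; a score of exactly 0.7 is
excluded). Concept level: the concept's semantic type is the *first*
entry of its mention's type list; when different mentions of one concept
disagree, the first surviving mention in corpus order decides
(deterministic, and disagreements are rare in linker output). Concepts
whose type is outside the allowlist (default: the packaged 26
disorder-relevant types), in the configurable blocklist (a stand-in for
manual false-positive review), or occurring in fewer than `min_doc_count`
documents (default 10) are dropped. Document level: condition synonyms
are first rewritten to the canonical condition id, then only documents
mentioning at least one configured condition are retained.

Condition concepts bypass the type and count filters (the anchor node
must always exist) but *not* the mention-level score cutoff; a condition
id may not appear in the blocklist (configuration error). The vocabulary
records the score cutoff it was built with, and all downstream occurrence
counting (co-occurrence, condition frequency) reuses it — this is what
makes the co-occurrence diagonal provably equal the vocabulary's document
counts.

Index assignment is by descending document count with lexicographic
concept-id tie-break, making the vocabulary a pure function of the
filtered corpus.

## PPMI and SVD

Probabilities are estimated as document proportions: p(i) = d_i/N,
p(i,j) = c_ij/N with N the filtered corpus size. PMI uses the natural
logarithm; the base is a pure convention because cosine relatedness is
invariant to positive scaling of the PPMI matrix (verified to 1e-9 in the
tests by scaling with 7.3). PMI is evaluated only on nonzero pair counts
— a zero count would give −∞ and clamps to 0 anyway — so no log-of-zero
warnings arise. The PPMI diagonal is zeroed by default
(`keep_diagonal=False`) so a concept's vector reflects its neighbourhood
rather than its own frequency, the common practice for PPMI-SVD vector
space models.

The embedding is exactly the rows of U_k S_k (not U_k, not U_k S_k^{1/2}).
k defaults to 300 and is clamped to the number of strictly positive
singular values (relative tolerance `s_max · max(n) · eps`). For
vocabularies up to n = 2000 the exact dense SVD is used; above that a
randomized SVD seeded from the pipeline seed keeps runs reproducible —
run-to-run stability is one reason to prefer count-based SVD embeddings
over stochastically trained neural embeddings in the first place. Column
signs follow the convention that the largest-magnitude entry of each left
singular vector is positive, making embeddings unique up to ties.

A subtlety worth knowing: if *every* filtered document mentioned the one
condition, then p(condition) = 1 and the condition's entire PPMI row is
ln(c_j/d_j) = 0 — there would be nothing to rank against. Real
condition-focused corpora avoid this because they are collected around
several conditions at once (so each condition covers only part of the
corpus), because some retained documents carry only sub-cutoff condition
mentions, or via title-only matches. The synthetic generator reproduces
the first mechanism (see below). Pipelines applied to a corpus where the
condition is literally universal will fail with a zero-vector error, by
design, rather than return meaningless ranks.

## Relatedness, ranking, graph

Cosine relatedness is clipped to [−1, 1] against rounding; a zero-norm
vector raises an error naming the concept instead of silently scoring 0.
Concept frequency is the proportion of condition-mentioning documents the
concept co-occurs with the condition in (denominator switchable to the
whole filtered corpus via `frequency_denominator: all_docs`; the default
makes frequencies comparable across corpora of different size). Within
each semantic type the top 25 concepts by relatedness are kept, ties
broken lexicographically; the condition is excluded from its own lists
(it is the hub, never a leaf), and concepts sharing the condition's
semantic type remain eligible under that type.

The property graph stores: condition node (frequency 1), semantic-type
nodes (frequency = arithmetic mean over the concepts actually selected,
which may be fewer than 25), concept nodes, `isA` edges weighted by
relatedness, unweighted `isRelatedTo` edges, and — after merging two
source graphs — one unweighted `sameAs` edge per concept selected in
*both* top lists, stored once with undirected semantics. Node ids are
namespaced `source:kind:key` so the same concept id can exist on both
sides. A validator enforces every schema invariant and is exercised by
perturbation tests. Export formats are GraphML (via networkx, exact
attribute round-trip) and a node/edge CSV pair suitable for graph-database
bulk importers; absent weights serialize as absent, never 0.

## Comparison

Score differences diff = FR − PR are computed over the intersection of
the two scored vocabularies (a concept absent from one corpus has no
score difference; source-exclusive concepts are reported separately,
uncategorized). The condition itself is excluded — its relatedness is 1 in
both corpora by construction, so it carries no information. µ is the mean
and σ the *population* standard deviation (divisor n; switchable to
sample via `ddof=1`). Classification uses strict inequalities, so
boundary values and the σ = 0 degenerate case are `similar`. One µ/σ pair
is computed per condition with all semantic types pooled. By default the
pipeline restricts the comparison to the union of the two top-25
selections (`compare_scope: selected`), since those are the concepts the
graphs display; `compare_scope: all` compares every shared concept.

## Synthetic data generator

`synthetic.generate_corpus` draws, per document, one latent topic
(uniform unless weighted), emits that topic's concepts independently with
their in-topic probabilities (default 0.8), emits every other topical
concept with a small leakage probability (default 0.02), and adds
topic-independent background concepts. Linker scores are sampled
uniformly from (0.75, 1.0) so nothing is lost to the 0.7 cutoff unless a
decoy fraction of deliberately sub-cutoff mentions is configured.
Generation is a pure function of (spec, seed).

The standard evaluation corpus (`default_spec`) has two topics of eight
concepts. Topic A carries the analysis condition `C_COND`; topic B
mirrors it with a second condition anchor `C_COND2`, emulating a corpus
collected around two conditions at once — which is also what keeps the
condition from saturating the filtered corpus (see above). The two
background "chatter" concepts carry generic semantic types ("qualitative
concept", "functional concept") that the default allowlist excludes:
topic-independent high-frequency concepts acquire spurious, bloc-aligned
PPMI noise (clamping at zero correlates their fluctuations with whichever
topic they randomly tilt toward), and the type allowlist is precisely the
mechanism that removes them. Bypassing the allowlist demonstrably lets
chatter concepts interleave into the rankings.

Ground truth: the condition's topic-mates must outrank every other
concept in relatedness to the condition. The evaluation (20 seeds × 1000
documents) runs with `min_doc_count=1`: at 0.02 leakage an out-of-topic
concept lands in only a handful of condition documents, and the ranking
check needs those concepts *present* in the vocabulary rather than
removed by the ≥10-document filter. This is part of the synthetic study
design; the pipeline default for real corpora remains 10.

What the generator does **not** emulate: real linker behaviour
(systematic false positives, abbreviation ambiguity), document length
variation and reply threads, correlated topics, polysemy, or realistic
score distributions. Passing the planted-structure tests therefore shows
the pipeline recovers clean co-occurrence structure and is internally
consistent; it does not certify performance on scraped forum text.

## Numerical and degenerate-input choices

- Empty corpus, empty vocabulary, absent condition, all-zero PPMI, and
  zero-norm vectors are explicit typed errors, surfaced by the pipeline
  with the failing stage's name.
- All tables are written with deterministic ordering and full float
  `repr`, and manifests as sorted-keys JSON without timestamps, so
  identical config + seed runs are byte-identical.
- Problem sizes used by the test suite and the acceptance script (corpora
  of 400–1000 documents, vocabularies of ~20 concepts, 20 evaluation
  seeds, 100 random PPMI-oracle corpora, 10,000 classifier draws) were
  chosen to exercise every code path at desk scale; all complete in
  seconds.

## Known limitations

- Relatedness is relative to a single condition vector; multi-condition
  corpora are supported for filtering but each analysis run anchors on
  one condition.
- PMI estimates from document proportions are noisy for rare concepts;
  the minimum-document filter is the only variance guard (no smoothing or
  context-distribution weighting is applied).
- The µ ± 2σ rule assumes the score-difference distribution is roughly
  unimodal; with heavy asymmetry between corpora the "similar" band can
  be wide.
- `sameAs` linking matches concept ids exactly; cross-vocabulary synonymy
  is assumed to have been resolved upstream by the annotator.
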