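# Methods

## Model

`pubfuse` ranks documents for a free-text query by fusing two bounded,
per-query-normalized relevance signals.

**Lexical signal.** The corpus is partitioned into per-publication-year
shards (records without a resolvable 4-digit year go to an `unknown`
shard). Each shard is an independent inverted index with its own document
count N, per-term document frequencies n(qᵢ), document lengths |d| and
their mean avgdl; a query is scored shard by shard with Okapi BM25
(natural-log IDF variant `ln((N − n + 0.5)/(n + 0.5) + 1)`, which is
strictly positive for every term), and the shard results are pooled. The
pooled raw scores are min–max normalized to `BM2501 ∈ [0,1)` with an
ε-guarded denominator `(s − min)/(max − min + ε)`; when every raw score is
equal the output is all zeros rather than NaN. Sharding by year makes
incremental (yearly) index updates and parallel search natural; because
IDF and avgdl are shard-local, a term's weight may differ across years —
this is a property of the sharded design, accepted deliberately.

**Semantic signal.** Every record's index text (title + abstract — the
identical string the lexical index sees) is embedded by a pluggable
encoder (deterministic `encode(text)`, fixed dimension). Retrieval is
exact brute-force cosine similarity with a cutoff `t`: scores below `t`
are excluded, not clamped, then the survivors are ranked and truncated.
Approximate backends can be substituted but must reproduce the exact
ranking on test scale.

**Fusion.** Each candidate in the union of the two top-m hit lists gets
exactly one final score

    FS = α·L + (1 − α)·S,   α(L) = 1/(1 + exp(−a(L − b))),

with L the normalized lexical score and S the (cutoff-filtered, else 0)
cosine. α depends on L only: strong exact-term evidence recruits the
lexical ranking, weak evidence defers to semantics. A candidate seen by
only one modality is back-filled on the other side — a semantic-only
document receives its true BM25 score from its year shard (often 0), a
lexical-only document its stored-vector cosine (floored to 0 below `t`).
The retrieved set is `R_τ = {d : FS > τ}` (strict), sorted by FS; FS ties
resolve toward the higher normalized lexical score, remaining ties
lexicographically by doc id.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k₁ | 1.5 | BM25 term-frequency saturation (conventional Okapi default) |
| b_len | 0.75 | BM25 length-normalization strength (Okapi default; named to avoid clashing with the sigmoid midpoint) |
| ε | 1e−9 | min–max denominator guard; any value ≪ typical score gaps behaves identically |
| a | 10 | sigmoid sharpness of the fusion weight |
| b | 0.5 | sigmoid midpoint; at L = 0.5 both modalities contribute equally |
| t | 0 | semantic cutoff; keeps cosines non-negative so S ∈ [0,1] |
| τ | 0.35 | retrieval threshold on FS; exposed on the CLI |
| top_m | 1000 | per-modality candidate pool before fusion; bounds the normalization population |

`a = 10, b = 0.5` are adopted as fixed constants of the method. τ and
top_m have no canonical values; the defaults are package choices and are
configurable everywhere.

## Normalization scope

Min–max normalization needs a population. It is computed here over the
*pooled candidate set of the query* (both modalities' top-m union), so the
best lexical candidate always normalizes to ≈ 1 regardless of shard layout,
and the scale is query-relative, not corpus-global. Consequence: the pool's
weakest lexical candidate maps to exactly 0 even if it matched a query term,
and a single-candidate pool maps to 0. With realistically sized pools this
only affects the tail of the ranking.

## Synthetic data

The generator emulates the conditions the method is meant to discriminate:
topics with two *disjoint* vocabularies (surface and paraphrase), documents
of 50–200 tokens drawn Zipf-weighted from the surface vocabulary (exercising
BM25 saturation and length normalization), titles that always contain the
topic's three core tokens, years uniform over a range (populating multiple
shards), and per-topic journals/authors/MeSH for the filter and facet
layers. Queries either reuse surface vocabulary (every exact-term query
shares a token with every relevant document, by construction) or use only
paraphrase vocabulary (zero token overlap — the lexically-dissimilar,
conceptually-related condition). Two deterministic encoders close the loop:
a `hash` encoder whose cosines track token overlap, and a `topic` encoder
that places same-topic texts within cosine ≥ 0.83 of each other
(orthonormal topic bases + bounded orthogonal perturbation) regardless of
overlap.

What passing tests on this test bed show: the machinery — sharded BM25,
pooled normalization, fusion algebra, threshold/tie semantics, metric
computation — is correct, and fusion behaves directionally as intended
(lexical-only collapses to NDCG 0 on paraphrase queries; the fused ranker
matches the stronger modality on each subset). What they do not show:
retrieval quality on real biomedical text, where topics overlap, vocabulary
is shared across topics, relevance is graded, and encoder geometry is far
less clean. Absolute metric values on the synthetic benchmark (often 1.0)
are therefore not comparable to published large-corpus figures.

Benchmark problem size — 2 topics × 200 documents, 40 queries, 64-dim
encoders — was chosen as the smallest scale at which every phenomenon of
interest (multi-shard search, pool normalization, both query regimes)
occurs; the whole benchmark runs in under a second.

## Numerical choices

* Natural log for IDF; this variant is bounded below by 0, so matched
  documents always score > 0 and candidate sets need no score floor.
* Cosine math always in float64, including for half-precision stores
  (dequantize-then-dot); float16 storage bounds per-coordinate error at
  ≤ 1e−3 on unit-scale inputs and pairwise-cosine error at ≤ 2e−3.
* Tokenization: lowercase, split on non-alphanumeric runs, no stemming
  (stopword removal exists behind a flag, default off) — deterministic and
  language-agnostic.
* Tie-breaks are total (score, then lexical score, then doc id), making
  every ranking deterministic and independent of shard/thread scheduling.
* Empty inputs: empty text tokenizes to `[]`; a query with no tokens *and*
  a zero-vector embedding is rejected as unanswerable; a token-less
  document is rejected at vector-store build time (cosine would be
  undefined).
* `retrieve` treats τ strictly (`FS > τ`), so τ = 1 provably returns
  nothing.

## Design decisions taken where the design was open

* Both pipelines index the same string (title + " " + abstract) —
  symmetry between modalities.
* Records with empty abstracts are kept and indexed by title.
* FS ties compare the *normalized* lexical score, since fusion operates
  after normalization.
* Filters post-filter the current result set (AND across facets, OR within
  a set-valued facet) and never re-trigger retrieval.
* MAP@k uses the min(|relevant|, k) denominator; NDCG uses binary gains
  with log₂(i+1) discount — the common trec_eval conventions.
* The relevance-bucket lower line (0.3) between Partially Relevant and
  Irrelevant is a package default; only the 0.5 Relevant line is canonical.
* Facet ties and ranking ties break alphabetically.

## Limitations

* No stemming/lemmatization or biomedical tokenization (hyphenated gene
  names split at the hyphen).
* Brute-force vector search only — adequate to ~10⁵ documents; no
  ANN/HNSW backends.
* Binary relevance only in the ranked metrics; no graded qrels.
* No Boolean/negation query semantics: negated concepts in a query will
  still *attract* semantically similar documents.
* The bundled encoders are test instruments, not language models; plugging
  in a production sentence encoder is the intended use for real corpora.
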