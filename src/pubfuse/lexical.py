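"""Per-year BM25 lexical indexing and scoring.

The lexical side of the hybrid ranker is Okapi BM25 evaluated over
*per-publication-year shards*: each shard carries its own corpus statistics
(document count ``N``, per-term document frequency ``n(q_i)``, document
lengths ``|d|`` and their mean ``avgdl``), so shards can be searched
independently (and concurrently) and the pooled result is identical to a
sequential scan.

Scores follow the standard formulation

    BM25(q, d) = sum_i IDF(q_i) * f(q_i, d) * (k1 + 1)
                        / (f(q_i, d) + k1 * (1 - b + b * |d| / avgdl))

    IDF(q_i)   = ln((N - n(q_i) + 0.5) / (n(q_i) + 0.5) + 1)

with natural logarithm; this IDF is strictly positive for every term.  Raw
pooled scores are rescaled per query to [0, 1) by an epsilon-guarded min-max
normalization (:func:`bm2501`) before fusion with the semantic score.
"""

from __future__ import annotations

import json
import math
import re
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .corpus import Corpus

INDEX_VERSION = 1

_TOKEN_RE = re.compile(r"[a-z0-9]+")

# Minimal English stopword list; removal is off by default.
STOPWORDS = frozenset(
    "a an and are as at be by for from has have in is it of on or that the "
    "this to was were which with".split()
)


def tokenize(text: str, remove_stopwords: bool = False) -> list[str]:
    """Lowercase and split on non-alphanumeric boundaries.

    Deterministic, language-agnostic, no stemming.  Empty text yields an
    empty list.
    """
    tokens = _TOKEN_RE.findall(text.lower())
    if remove_stopwords:
        tokens = [t for t in tokens if t not in STOPWORDS]
    return tokens


@dataclass(frozen=True)
class LexicalParams:
    """BM25 hyper-parameters.

    ``k1`` controls term-frequency saturation, ``b_len`` the strength of
    document-length normalization (the classical BM25 *b*, named ``b_len``
    here to avoid collision with the fusion sigmoid's midpoint *b*).
    Defaults are the conventional Okapi settings.
    """

    k1: float = 1.5
    b_len: float = 0.75
    remove_stopwords: bool = False

    def __post_init__(self) -> None:
        if self.k1 <= 0:
            raise ValueError("k1 must be positive")
        if not 0.0 <= self.b_len <= 1.0:
            raise ValueError("b_len must lie in [0, 1]")


@dataclass
class LexicalShard:
    """Inverted index over one publication year (or the ``unknown`` shard).

    ``postings`` maps term -> {doc_id -> term frequency}; ``doc_freq`` maps
    term -> number of documents containing it; ``doc_len`` maps doc_id ->
    token count.  ``avgdl`` is the mean of ``doc_len`` over the shard and
    ``N = len(doc_len)``.
    """

    shard_key: str
    doc_len: dict[str, int] = field(default_factory=dict)
    postings: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def n_docs(self) -> int:
        return len(self.doc_len)

    @property
    def avgdl(self) -> float:
        if not self.doc_len:
            return 0.0
        return sum(self.doc_len.values()) / len(self.doc_len)

    def doc_freq(self, term: str) -> int:
        return len(self.postings.get(term, ()))

    def add_document(self, doc_id: str, tokens: list[str]) -> None:
        if doc_id in self.doc_len:
            raise ValueError(f"doc_id {doc_id!r} already indexed in shard")
        self.doc_len[doc_id] = len(tokens)
        for tok in tokens:
            docs = self.postings.setdefault(tok, {})
            docs[doc_id] = docs.get(doc_id, 0) + 1


def build_shards(
    corpus: Corpus, params: LexicalParams | None = None
) -> dict[str, LexicalShard]:
    """Partition the corpus by publication year and index each partition.

    Every record lands in exactly one shard, keyed by its year (or
    ``"unknown"``); shard statistics are local to the partition.
    """
    params = params or LexicalParams()
    shards: dict[str, LexicalShard] = {}
    for rec in corpus:
        key = rec.shard_key
        shard = shards.setdefault(key, LexicalShard(shard_key=key))
        shard.add_document(rec.doc_id, tokenize(rec.index_text, params.remove_stopwords))
    return shards


def idf(term: str, shard: LexicalShard) -> float:
    """ln((N - n + 0.5) / (n + 0.5) + 1); a term absent from the shard uses n=0."""
    n = shard.doc_freq(term)
    big_n = shard.n_docs
    return math.log((big_n - n + 0.5) / (n + 0.5) + 1.0)


def bm25_score(
    query_tokens: Iterable[str],
    doc_id: str,
    shard: LexicalShard,
    params: LexicalParams | None = None,
) -> float:
    """BM25 score of one document for a tokenized query (shard-local stats)."""
    params = params or LexicalParams()
    if doc_id not in shard.doc_len:
        raise KeyError(f"doc_id {doc_id!r} not present in shard {shard.shard_key!r}")
    dl = shard.doc_len[doc_id]
    avgdl = shard.avgdl
    score = 0.0
    for term in query_tokens:
        f = shard.postings.get(term, {}).get(doc_id, 0)
        if f == 0:
            continue
        denom = f + params.k1 * (1.0 - params.b_len + params.b_len * dl / avgdl)
        score += idf(term, shard) * f * (params.k1 + 1.0) / denom
    return score


def _search_shard(
    shard: LexicalShard, query_tokens: list[str], params: LexicalParams
) -> list[tuple[str, float]]:
    candidates: set[str] = set()
    for term in query_tokens:
        candidates.update(shard.postings.get(term, ()))
    return [
        (doc_id, bm25_score(query_tokens, doc_id, shard, params))
        for doc_id in candidates
    ]


def lexical_search(
    query_tokens: list[str],
    shards: Mapping[str, LexicalShard],
    top_m: int,
    params: LexicalParams | None = None,
    n_jobs: int = 1,
) -> list[tuple[str, float]]:
    """Score every matching document in every shard and pool the results.

    Each shard is scored with its own statistics; only documents containing
    at least one query term are candidates (their BM25 score is strictly
    positive).  The pooled list is sorted by raw score descending with
    lexicographic doc_id tie-break and truncated to ``top_m``.  Shards may be
    searched concurrently (``n_jobs > 1``); the result is identical to
    sequential execution.
    """
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    params = params or LexicalParams()
    ordered = [shards[k] for k in sorted(shards)]
    if n_jobs > 1 and len(ordered) > 1:
        with ThreadPoolExecutor(max_workers=n_jobs) as pool:
            per_shard = list(
                pool.map(lambda s: _search_shard(s, query_tokens, params), ordered)
            )
    else:
        per_shard = [_search_shard(s, query_tokens, params) for s in ordered]
    pooled = [hit for hits in per_shard for hit in hits]
    pooled.sort(key=lambda h: (-h[1], h[0]))
    return pooled[:top_m]


def bm2501(raw_scores: list[float], epsilon: float = 1e-9) -> list[float]:
    """Min-max normalize raw BM25 scores to [0, 1) with an epsilon guard.

    Each score s maps to (s - min) / (max - min + epsilon); when all scores
    are equal the denominator is epsilon and every output is exactly 0 (no
    NaN).  The mapping is monotone, so ranking order is preserved.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if not raw_scores:
        return []
    lo = min(raw_scores)
    hi = max(raw_scores)
    denom = hi - lo + epsilon
    return [(s - lo) / denom for s in raw_scores]


# ---------------------------------------------------------------------------
# Shard serialization: single JSON file, term dictionaries sorted so the byte
# output is reproducible for a fixed corpus.
# ---------------------------------------------------------------------------

def save_shards(
    shards: Mapping[str, LexicalShard], params: LexicalParams, path: str | Path
) -> None:
    payload = {
        "index_version": INDEX_VERSION,
        "params": {
            "k1": params.k1,
            "b_len": params.b_len,
            "remove_stopwords": params.remove_stopwords,
        },
        "shards": {
            key: {
                "doc_len": dict(sorted(shards[key].doc_len.items())),
                "postings": {
                    term: dict(sorted(docs.items()))
                    for term, docs in sorted(shards[key].postings.items())
                },
            }
            for key in sorted(shards)
        },
    }
    Path(path).write_text(json.dumps(payload, ensure_ascii=False), encoding="utf-8")


def load_shards(path: str | Path) -> tuple[dict[str, LexicalShard], LexicalParams]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("index_version") != INDEX_VERSION:
        raise ValueError(
            f"lexical index version {payload.get('index_version')!r} "
            f"!= expected {INDEX_VERSION}"
        )
    params = LexicalParams(**payload["params"])
    shards = {
        key: LexicalShard(
            shard_key=key, doc_len=data["doc_len"], postings=data["postings"]
        )
        for key, data in payload["shards"].items()
    }
    return shards, params


__all__ = [
    "INDEX_VERSION",
    "STOPWORDS",
    "LexicalParams",
    "LexicalShard",
    "tokenize",
    "build_shards",
    "idf",
    "bm25_score",
    "lexical_search",
    "bm2501",
    "save_shards",
    "load_shards",
]
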