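"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's index structures: scores are
recomputed from raw token lists and rankings are evaluated with plain
loops, so agreement with the package is a genuine cross-check rather than
a tautology.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence


def brute_force_bm25(
    query_tokens: Sequence[str],
    doc_tokens: Mapping[str, list[str]],
    target_doc: str,
    k1: float = 1.5,
    b: float = 0.75,
) -> float:
    """Evaluate BM25 directly from the token lists of a (sub)corpus."""
    n_docs = len(doc_tokens)
    lengths = {d: len(toks) for d, toks in doc_tokens.items()}
    avgdl = sum(lengths.values()) / n_docs
    score = 0.0
    for term in query_tokens:
        n_t = sum(1 for toks in doc_tokens.values() if term in toks)
        idf = math.log((n_docs - n_t + 0.5) / (n_t + 0.5) + 1.0)
        f = doc_tokens[target_doc].count(term)
        if f == 0:
            continue
        norm = k1 * (1.0 - b + b * lengths[target_doc] / avgdl)
        score += idf * f * (k1 + 1.0) / (f + norm)
    return score


def brute_force_bm25_ranking(
    query_tokens: Sequence[str],
    doc_tokens: Mapping[str, list[str]],
    k1: float = 1.5,
    b: float = 0.75,
) -> list[tuple[str, float]]:
    """Global BM25 ranking of all docs sharing a term with the query."""
    hits = []
    for doc_id, toks in doc_tokens.items():
        if any(t in toks for t in query_tokens):
            hits.append(
                (doc_id, brute_force_bm25(query_tokens, doc_tokens, doc_id, k1, b))
            )
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits


def ref_ndcg(ranking: Sequence[str], relevant: set[str], k: int) -> float:
    gains = [1.0 if d in relevant else 0.0 for d in ranking[:k]]
    dcg = 0.0
    for i, g in enumerate(gains):
        dcg += g / math.log2(i + 2)
    ideal = 0.0
    for i in range(min(k, len(relevant))):
        ideal += 1.0 / math.log2(i + 2)
    return dcg / ideal if ideal else 0.0


def ref_average_precision(ranking: Sequence[str], relevant: set[str], k: int) -> float:
    num_rel_seen = 0
    total = 0.0
    for idx in range(min(k, len(ranking))):
        if ranking[idx] in relevant:
            num_rel_seen += 1
            total += num_rel_seen / (idx + 1)
    return total / min(len(relevant), k) if relevant else 0.0


def ref_reciprocal_rank(ranking: Sequence[str], relevant: set[str], k: int) -> float:
    for idx in range(min(k, len(ranking))):
        if ranking[idx] in relevant:
            return 1.0 / (idx + 1)
    return 0.0
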