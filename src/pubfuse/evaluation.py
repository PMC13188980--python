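"""Ranked-retrieval evaluation: NDCG / MAP / MRR plus a cosine-proxy protocol.

Binary-relevance metrics at configurable rank cutoffs (default 5, 10, 15,
100), fed by TREC-style qrels and run files:

* ``NDCG@k`` — DCG@k = sum_{i<=k} rel_i / log2(i + 1), normalized by the
  ideal DCG for the query's relevant-set size.
* ``MAP@k``  — average of Precision@i over relevant hits at ranks i <= k,
  divided by min(|relevant|, k) (trec_eval convention).
* ``MRR@k``  — reciprocal rank of the first relevant hit within the top k,
  else 0.

The cosine-proxy protocol scores a system by the mean query-result cosine
similarity over its top K results (K = 3 by default) and buckets each result
by similarity: >= 0.5 is Relevant, below 0.3 Irrelevant, in between
Partially Relevant; a query with no results is reported as missing, which is
distinct from scoring 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .semantic import EncoderContract, cosim

logger = logging.getLogger(__name__)

DEFAULT_CUTOFFS = (5, 10, 15, 100)

RELEVANT = "Relevant"
PARTIALLY_RELEVANT = "PartiallyRelevant"
IRRELEVANT = "Irrelevant"


@dataclass
class JudgmentSet:
    """query_id -> set of relevant doc_ids (binary relevance)."""

    relevant: dict[str, set[str]] = field(default_factory=dict)

    def __getitem__(self, query_id: str) -> set[str]:
        return self.relevant[query_id]

    def __contains__(self, query_id: str) -> bool:
        return query_id in self.relevant

    def query_ids(self) -> list[str]:
        return sorted(self.relevant)


@dataclass
class RunFile:
    """query_id -> ranked doc_id list; no duplicates within a ranking."""

    rankings: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for qid, ranking in self.rankings.items():
            if len(set(ranking)) != len(ranking):
                raise ValueError(f"duplicate doc_ids in ranking for query {qid!r}")


def ndcg_at_k(ranking: Sequence[str], relevant_set: set[str], k: int) -> float:
    """Binary-gain NDCG at cutoff k; 0 if no relevant document is retrieved."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not relevant_set:
        raise ValueError("NDCG undefined for an empty relevant set")
    dcg = sum(
        1.0 / math.log2(i + 2)
        for i, doc_id in enumerate(ranking[:k])
        if doc_id in relevant_set
    )
    ideal = sum(1.0 / math.log2(i + 2) for i in range(min(k, len(relevant_set))))
    return dcg / ideal


def map_at_k(ranking: Sequence[str], relevant_set: set[str], k: int) -> float:
    """Average precision at cutoff k with denominator min(|relevant|, k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not relevant_set:
        raise ValueError("AP undefined for an empty relevant set")
    hits = 0
    precision_sum = 0.0
    for i, doc_id in enumerate(ranking[:k], start=1):
        if doc_id in relevant_set:
            hits += 1
            precision_sum += hits / i
    return precision_sum / min(len(relevant_set), k)


def mrr_at_k(ranking: Sequence[str], relevant_set: set[str], k: int) -> float:
    """Reciprocal rank of the first relevant document within the top k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not relevant_set:
        raise ValueError("MRR undefined for an empty relevant set")
    for i, doc_id in enumerate(ranking[:k], start=1):
        if doc_id in relevant_set:
            return 1.0 / i
    return 0.0


_METRICS = {"ndcg": ndcg_at_k, "map": map_at_k, "mrr": mrr_at_k}


def evaluate_run(
    run: RunFile,
    judgments: JudgmentSet,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
) -> dict[str, dict[int, float]]:
    """Mean NDCG/MAP/MRR over judged queries at each cutoff.

    Queries judged but absent from the run score 0 on every metric; queries
    with an empty relevant set are skipped with a warning.  Raises if the
    run and the judgments share no scoreable query.
    """
    scoreable = [
        qid for qid in judgments.query_ids() if judgments[qid]
    ]
    for qid in judgments.query_ids():
        if not judgments[qid]:
            logger.warning("query %s has an empty relevant set; skipped", qid)
    if not scoreable or not any(qid in run.rankings for qid in scoreable):
        raise ValueError("no overlapping queries between run and judgments")
    table: dict[str, dict[int, float]] = {
        name: {k: 0.0 for k in cutoffs} for name in _METRICS
    }
    for qid in scoreable:
        ranking = run.rankings.get(qid, [])
        for name, fn in _METRICS.items():
            for k in cutoffs:
                table[name][k] += fn(ranking, judgments[qid], k)
    n = len(scoreable)
    return {name: {k: v / n for k, v in row.items()} for name, row in table.items()}


def format_metric_table(table: Mapping[str, Mapping[int, float]]) -> str:
    """Render the metric table as TSV (metrics as rows, cutoffs as columns)."""
    cutoffs = sorted(next(iter(table.values())))
    lines = ["metric\t" + "\t".join(f"@{k}" for k in cutoffs)]
    for name in sorted(table):
        lines.append(
            name + "\t" + "\t".join(f"{table[name][k]:.4f}" for k in cutoffs)
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Cosine-proxy protocol (mean top-K cosine + relevance bucketing)
# ---------------------------------------------------------------------------

def mean_cosine_topk(
    query: str,
    result_abstracts: Sequence[str],
    encoder: EncoderContract,
    k: int = 3,
) -> float | None:
    """Mean cosine between the query and the abstracts of the top K results.

    Returns ``None`` (missing) when there are no results — deliberately
    distinct from a score of 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not result_abstracts:
        return None
    qvec = np.asarray(encoder.encode(query), dtype=np.float64)
    sims = [
        cosim(qvec, np.asarray(encoder.encode(text), dtype=np.float64))
        for text in result_abstracts[:k]
    ]
    return float(np.mean(sims))


def bucket_relevance(
    cosine: float, upper: float = 0.5, lower: float = 0.3
) -> str:
    """Bucket a query-result cosine: >= upper Relevant, < lower Irrelevant."""
    if lower > upper:
        raise ValueError("thresholds must satisfy lower <= upper")
    if cosine >= upper:
        return RELEVANT
    if cosine < lower:
        return IRRELEVANT
    return PARTIALLY_RELEVANT


# ---------------------------------------------------------------------------
# TREC-style text I/O
# ---------------------------------------------------------------------------

def read_qrels(path: str | Path) -> JudgmentSet:
    """Read TREC qrels lines ``query_id 0 doc_id rel``; rel > 0 is relevant."""
    judgments = JudgmentSet()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        qid, _, doc_id, rel = line.split()
        judgments.relevant.setdefault(qid, set())
        if int(rel) > 0:
            judgments.relevant[qid].add(doc_id)
    return judgments


def write_qrels(judgments: JudgmentSet, path: str | Path) -> None:
    lines = [
        f"{qid} 0 {doc_id} 1"
        for qid in judgments.query_ids()
        for doc_id in sorted(judgments[qid])
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_run(path: str | Path) -> RunFile:
    """Read TREC run lines ``query_id Q0 doc_id rank score tag`` (rank order)."""
    per_query: dict[str, list[tuple[int, str]]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.split()
        qid, doc_id, rank = parts[0], parts[2], int(parts[3])
        per_query.setdefault(qid, []).append((rank, doc_id))
    return RunFile(
        rankings={
            qid: [doc_id for _, doc_id in sorted(entries)]
            for qid, entries in per_query.items()
        }
    )


def write_run(run: RunFile, path: str | Path, tag: str = "pubfuse") -> None:
    lines = []
    for qid in sorted(run.rankings):
        for rank, doc_id in enumerate(run.rankings[qid], start=1):
            score = 1.0 / rank
            lines.append(f"{qid} Q0 {doc_id} {rank} {score:.6f} {tag}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


__all__ = [
    "DEFAULT_CUTOFFS",
    "RELEVANT",
    "PARTIALLY_RELEVANT",
    "IRRELEVANT",
    "JudgmentSet",
    "RunFile",
    "ndcg_at_k",
    "map_at_k",
    "mrr_at_k",
    "evaluate_run",
    "format_metric_table",
    "mean_cosine_topk",
    "bucket_relevance",
    "read_qrels",
    "write_qrels",
    "read_run",
    "write_run",
]
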