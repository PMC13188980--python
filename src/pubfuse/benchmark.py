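"""End-to-end synthetic benchmark: hybrid retrieval vs single-modality ablations.

Builds a topic-encoder corpus, runs every query through the full engine in
three configurations — adaptive fusion, lexical-only (alpha fixed at 1), and
semantic-only (alpha fixed at 0) — and evaluates ranked-retrieval metrics
separately on exact-term and paraphrase query subsets.  The paraphrase
subset is the condition where purely lexical retrieval fails by
construction (zero token overlap with relevant documents); the exact-term
subset is where keyword precision matters.

Also computes the cosine-proxy protocol on the hybrid system: the mean
query-result cosine over the top K=3 abstracts and the distribution of
results over Relevant / PartiallyRelevant / Irrelevant buckets.
"""

from __future__ import annotations

from dataclasses import replace

from .evaluation import (
    JudgmentSet,
    RunFile,
    bucket_relevance,
    evaluate_run,
    mean_cosine_topk,
)
from .fusion import FusionParams, HybridSearchEngine
from .semantic import cosim
from .synthetic import (
    QueryRecord,
    SyntheticEncoder,
    generate_corpus,
    generate_eval_set,
    make_topics,
)

SYSTEMS = ("hybrid", "lexical", "semantic")


def build_benchmark(
    seed: int,
    n_topics: int = 2,
    docs_per_topic: int = 200,
    n_queries: int = 40,
    paraphrase_fraction: float = 0.5,
    dim: int = 64,
    tau: float = 0.35,
):
    """Generate the corpus, queries, judgments, and engine for one seed."""
    topics = make_topics(n_topics, dim=dim, seed=seed)
    corpus = generate_corpus(n_topics * docs_per_topic, topics, seed=seed)
    encoder = SyntheticEncoder(mode="topic", dim=dim, seed=seed, topics=topics)
    engine = HybridSearchEngine.build(
        corpus, encoder, fusion_params=FusionParams(tau=tau)
    )
    queries, judgments = generate_eval_set(
        corpus, topics, n_queries, paraphrase_fraction, seed=seed
    )
    return engine, queries, judgments


def run_system(
    engine: HybridSearchEngine,
    queries: list[QueryRecord],
    system: str,
    max_results: int = 100,
) -> RunFile:
    """Produce a run file for one system variant over all queries."""
    if system == "hybrid":
        params = engine.fusion_params
    elif system == "lexical":
        params = replace(engine.fusion_params, alpha_override=1.0)
    elif system == "semantic":
        params = replace(engine.fusion_params, alpha_override=0.0)
    else:
        raise ValueError(f"unknown system {system!r}")
    rankings = {}
    for query in queries:
        results = engine.retrieve(query.text, params=params, max_results=max_results)
        rankings[query.query_id] = [c.doc_id for c in results]
    return RunFile(rankings=rankings)


def _subset(
    run: RunFile, judgments: JudgmentSet, queries: list[QueryRecord], paraphrase: bool
) -> tuple[RunFile, JudgmentSet]:
    ids = {q.query_id for q in queries if q.paraphrase is paraphrase}
    return (
        RunFile(rankings={q: r for q, r in run.rankings.items() if q in ids}),
        JudgmentSet(relevant={q: s for q, s in judgments.relevant.items() if q in ids}),
    )


def run_synthetic_benchmark(
    seed: int,
    n_topics: int = 2,
    docs_per_topic: int = 200,
    n_queries: int = 40,
    cutoffs: tuple[int, ...] = (5, 10, 15, 100),
    topk_cosine: int = 3,
) -> dict:
    """Full ablation benchmark; returns metric tables and proxy statistics.

    Returns a dict with ``metrics[system][subset][metric][k]`` (subset in
    {"exact", "paraphrase", "all"}), ``mean_cosine_top3`` for the hybrid
    system, and ``relevance_proportions`` over its retrieved top-K results.
    """
    engine, queries, judgments = build_benchmark(
        seed, n_topics=n_topics, docs_per_topic=docs_per_topic, n_queries=n_queries
    )
    runs = {system: run_system(engine, queries, system) for system in SYSTEMS}

    metrics: dict[str, dict[str, dict]] = {}
    for system, run in runs.items():
        metrics[system] = {"all": evaluate_run(run, judgments, cutoffs)}
        for subset_name, is_para in (("exact", False), ("paraphrase", True)):
            sub_run, sub_judg = _subset(run, judgments, queries, is_para)
            metrics[system][subset_name] = evaluate_run(sub_run, sub_judg, cutoffs)

    # Cosine-proxy protocol on the hybrid system.
    cosines = []
    buckets = {"Relevant": 0, "PartiallyRelevant": 0, "Irrelevant": 0, "NoResults": 0}
    per_result_buckets = {"Relevant": 0, "PartiallyRelevant": 0, "Irrelevant": 0}
    n_results = 0
    for query in queries:
        top = runs["hybrid"].rankings[query.query_id][:topk_cosine]
        abstracts = [engine.corpus[d].abstract for d in top]
        mean_cos = mean_cosine_topk(query.text, abstracts, engine.encoder, topk_cosine)
        if mean_cos is None:
            buckets["NoResults"] += 1
            continue
        cosines.append(mean_cos)
        qvec = engine.encoder.encode(query.text)
        for text in abstracts:
            label = bucket_relevance(cosim(qvec, engine.encoder.encode(text)))
            per_result_buckets[label] += 1
            n_results += 1
    mean_cosine = sum(cosines) / len(cosines) if cosines else None
    proportions = {
        label: (count / n_results if n_results else 0.0)
        for label, count in per_result_buckets.items()
    }
    return {
        "metrics": metrics,
        "mean_cosine_top3": mean_cosine,
        "relevance_proportions": proportions,
        "n_queries_no_results": buckets["NoResults"],
        "n_docs": len(engine.corpus),
        "n_queries": len(queries),
    }


__all__ = ["SYSTEMS", "build_benchmark", "run_system", "run_synthetic_benchmark"]
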