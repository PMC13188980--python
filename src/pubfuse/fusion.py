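"""Sigmoid-adaptive fusion of lexical and semantic scores.

Both retrieval modalities produce a score in [0, 1] per candidate document:
the min-max-normalized BM25 score (``bm2501``, written L below) and the
cutoff-filtered cosine similarity (``cosim``, S).  They are fused into one
final score per document

    FS = alpha * L + (1 - alpha) * S,     alpha = 1 / (1 + exp(-a * (L - b)))

where the adaptive weight ``alpha`` is a sigmoid of the *normalized lexical
score only*: a strong exact-term match (L near 1) pushes alpha toward 1 and
lets lexical evidence dominate, while a weak match (L near 0) hands the
ranking to semantic similarity.  The sharpness ``a = 10`` and midpoint
``b = 0.5`` give a balanced transition; at L = 0.5 the two modalities
contribute equally.

The retrieved set is R_tau = {d | FS(q, d) > tau} — strict inequality —
sorted by FS descending; FS ties are resolved in favour of the higher
lexical score, remaining ties lexicographically by doc_id.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus import Corpus, load_corpus, save_corpus
from .lexical import (
    LexicalParams,
    LexicalShard,
    bm25_score,
    bm2501,
    build_shards,
    lexical_search,
    load_shards,
    save_shards,
    tokenize,
)
from .semantic import (
    EncoderContract,
    VectorStore,
    build_vector_store,
    cosim as _cosim,
    semantic_search,
)

MANIFEST_VERSION = 1


class UnanswerableQueryError(ValueError):
    """Query with no indexable tokens and a zero-vector embedding."""


@dataclass(frozen=True)
class FusionParams:
    """Fusion and retrieval parameters.

    a_sharp, b_mid   sigmoid sharpness and midpoint of the adaptive weight
                     (defaults 10 and 0.5)
    tau              retrieval threshold; only FS > tau is returned
    epsilon          guard constant of the lexical min-max normalization
    t_cutoff         semantic cutoff; cosines below it are discarded
    top_m            per-modality candidate pool size before fusion
    alpha_override   fix alpha to a constant (0 => pure semantic, 1 => pure
                     lexical); None for the adaptive sigmoid.  Used for
                     ablations.
    """

    a_sharp: float = 10.0
    b_mid: float = 0.5
    tau: float = 0.35
    epsilon: float = 1e-9
    t_cutoff: float = 0.0
    top_m: int = 1000
    alpha_override: float | None = None

    def __post_init__(self) -> None:
        if self.a_sharp <= 0:
            raise ValueError("a_sharp must be positive")
        if not 0.0 <= self.b_mid <= 1.0:
            raise ValueError("b_mid must lie in [0, 1]")
        if not 0.0 <= self.tau < 1.0:
            raise ValueError("tau must lie in [0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.alpha_override is not None and not 0.0 <= self.alpha_override <= 1.0:
            raise ValueError("alpha_override must lie in [0, 1]")


@dataclass(frozen=True)
class ScoredCandidate:
    """Per-document score bundle produced at query time."""

    doc_id: str
    raw_bm25: float
    bm2501: float
    cosim: float
    alpha: float
    fs: float


def adaptive_alpha(bm2501_score: float, params: FusionParams | None = None) -> float:
    """Sigmoid weight 1 / (1 + exp(-a * (x - b))); strictly increasing in x."""
    params = params or FusionParams()
    if params.alpha_override is not None:
        return params.alpha_override
    return 1.0 / (1.0 + math.exp(-params.a_sharp * (bm2501_score - params.b_mid)))


def final_score(
    bm2501_score: float, cosim_score: float, params: FusionParams | None = None
) -> float:
    """FS = alpha * L + (1 - alpha) * S with alpha = adaptive_alpha(L).

    A convex combination, so FS always lies between its two arguments.
    Inputs outside [0, 1] violate the upstream normalization contract and
    raise.
    """
    params = params or FusionParams()
    if not 0.0 <= bm2501_score <= 1.0:
        raise ValueError(f"bm2501 score {bm2501_score} outside [0, 1]")
    if not 0.0 <= cosim_score <= 1.0:
        raise ValueError(f"cosim score {cosim_score} outside [0, 1]")
    alpha = adaptive_alpha(bm2501_score, params)
    return alpha * bm2501_score + (1.0 - alpha) * cosim_score


def aggregate_candidates(
    lexical_hits: Sequence[tuple[str, float]],
    semantic_hits: Sequence[tuple[str, float]],
    shards: Mapping[str, LexicalShard],
    store: VectorStore,
    query_tokens: list[str],
    query_vec: np.ndarray | None,
    corpus: Corpus,
    params: FusionParams | None = None,
    lexical_params: LexicalParams | None = None,
) -> list[ScoredCandidate]:
    """Union the two hit lists and give every member exactly one final score.

    A document retrieved by only one modality is back-filled on the other
    side: a semantic-only document gets its true BM25 score from its year
    shard (0 if it shares no query term); a lexical-only document gets its
    stored-vector cosine, floored to 0 when below the cutoff ``t``.  The
    min-max normalization to bm2501 runs over the *pooled* raw BM25 scores,
    so the best lexical candidate normalizes to ~1.
    """
    params = params or FusionParams()
    sem = dict(semantic_hits)
    lex = dict(lexical_hits)
    pool = sorted(set(lex) | set(sem))
    for doc_id in pool:
        if doc_id not in corpus:
            raise KeyError(f"candidate {doc_id!r} not present in corpus")

    raw_scores = []
    for doc_id in pool:
        if doc_id in lex:
            raw_scores.append(lex[doc_id])
        else:
            shard = shards[corpus[doc_id].shard_key]
            raw_scores.append(bm25_score(query_tokens, doc_id, shard, lexical_params))

    cos_scores = []
    for doc_id in pool:
        if doc_id in sem:
            cos_scores.append(sem[doc_id])
        elif query_vec is not None:
            c = _cosim(query_vec, store.get(doc_id))
            cos_scores.append(c if c >= params.t_cutoff else 0.0)
        else:
            cos_scores.append(0.0)

    norm = bm2501(raw_scores, params.epsilon)
    out = []
    for doc_id, raw, lx, cs in zip(pool, raw_scores, norm, cos_scores):
        alpha = adaptive_alpha(lx, params)
        out.append(
            ScoredCandidate(
                doc_id=doc_id,
                raw_bm25=raw,
                bm2501=lx,
                cosim=cs,
                alpha=alpha,
                fs=alpha * lx + (1.0 - alpha) * cs,
            )
        )
    return out


def rank_candidates(
    candidates: Sequence[ScoredCandidate],
    tau: float,
    max_results: int | None = None,
) -> list[ScoredCandidate]:
    """Apply the strict FS > tau filter and the tie-break order."""
    kept = [c for c in candidates if c.fs > tau]
    kept.sort(key=lambda c: (-c.fs, -c.bm2501, c.doc_id))
    return kept[:max_results] if max_results is not None else kept


class HybridSearchEngine:
    """Corpus + per-year lexical shards + vector store, queried as one unit.

    Build once with :meth:`build`, then call :meth:`retrieve` for fused
    ranked retrieval or :meth:`similar_articles` for cosine-only
    related-document lookup.  State round-trips through :meth:`save` /
    :meth:`load` (the encoder itself is supplied at load time; the manifest
    records its name and dimension and refuses a mismatched encoder).
    """

    def __init__(
        self,
        corpus: Corpus,
        shards: Mapping[str, LexicalShard],
        store: VectorStore,
        encoder: EncoderContract,
        lexical_params: LexicalParams | None = None,
        fusion_params: FusionParams | None = None,
    ) -> None:
        self.corpus = corpus
        self.shards = dict(shards)
        self.store = store
        self.encoder = encoder
        self.lexical_params = lexical_params or LexicalParams()
        self.fusion_params = fusion_params or FusionParams()

    @classmethod
    def build(
        cls,
        corpus: Corpus,
        encoder: EncoderContract,
        lexical_params: LexicalParams | None = None,
        fusion_params: FusionParams | None = None,
        precision: str = "full",
    ) -> "HybridSearchEngine":
        lexical_params = lexical_params or LexicalParams()
        return cls(
            corpus=corpus,
            shards=build_shards(corpus, lexical_params),
            store=build_vector_store(corpus, encoder, precision),
            encoder=encoder,
            lexical_params=lexical_params,
            fusion_params=fusion_params,
        )

    def score_pool(
        self, query: str, params: FusionParams | None = None, n_jobs: int = 1
    ) -> list[ScoredCandidate]:
        """Tokenize + embed the query and score the pooled candidate set."""
        params = params or self.fusion_params
        tokens = tokenize(query, self.lexical_params.remove_stopwords)
        qvec = np.asarray(self.encoder.encode(query), dtype=np.float64)
        has_vec = bool(np.linalg.norm(qvec) > 0.0)
        if not tokens and not has_vec:
            raise UnanswerableQueryError(
                f"unanswerable query: {query!r} has no tokens and a zero embedding"
            )
        lex_hits = (
            lexical_search(tokens, self.shards, params.top_m, self.lexical_params, n_jobs)
            if tokens
            else []
        )
        sem_hits = (
            semantic_search(qvec, self.store, params.t_cutoff, params.top_m)
            if has_vec
            else []
        )
        return aggregate_candidates(
            lex_hits,
            sem_hits,
            self.shards,
            self.store,
            tokens,
            qvec if has_vec else None,
            self.corpus,
            params,
            self.lexical_params,
        )

    def retrieve(
        self,
        query: str,
        params: FusionParams | None = None,
        max_results: int | None = None,
        n_jobs: int = 1,
    ) -> list[ScoredCandidate]:
        """Ranked retrieval: candidates with FS > tau, fully tie-broken."""
        params = params or self.fusion_params
        candidates = self.score_pool(query, params, n_jobs)
        return rank_candidates(candidates, params.tau, max_results)

    def similar_articles(self, doc_id: str, k: int = 10) -> list[tuple[str, float]]:
        """Cosine-only ranking of all other documents against ``doc_id``."""
        ref = self.store.get(doc_id)  # raises KeyError if unknown
        hits = [
            (other, score)
            for other, score in zip(self.store.doc_ids, self.store.cosims(ref))
            if other != doc_id
        ]
        hits.sort(key=lambda h: (-h[1], h[0]))
        return [(d, float(s)) for d, s in hits[:k]]

    # -- persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_corpus(self.corpus, directory / "corpus.json")
        save_shards(self.shards, self.lexical_params, directory / "lexical.json")
        self.store.save(directory / "vectors.bin")
        manifest = {
            "manifest_version": MANIFEST_VERSION,
            "encoder": {"name": self.encoder.name, "dim": self.encoder.dim},
            "precision": self.store.precision,
            "fusion_params": {
                "a_sharp": self.fusion_params.a_sharp,
                "b_mid": self.fusion_params.b_mid,
                "tau": self.fusion_params.tau,
                "epsilon": self.fusion_params.epsilon,
                "t_cutoff": self.fusion_params.t_cutoff,
                "top_m": self.fusion_params.top_m,
            },
        }
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2), encoding="utf-8"
        )

    @classmethod
    def load(cls, directory: str | Path, encoder: EncoderContract) -> "HybridSearchEngine":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text(encoding="utf-8"))
        if manifest.get("manifest_version") != MANIFEST_VERSION:
            raise ValueError("unsupported engine manifest version")
        want = manifest["encoder"]
        if want["name"] != encoder.name or want["dim"] != encoder.dim:
            raise ValueError(
                f"encoder mismatch: index built with {want}, got "
                f"{{'name': {encoder.name!r}, 'dim': {encoder.dim}}}"
            )
        shards, lexical_params = load_shards(directory / "lexical.json")
        return cls(
            corpus=load_corpus(directory / "corpus.json"),
            shards=shards,
            store=VectorStore.load(directory / "vectors.bin"),
            encoder=encoder,
            lexical_params=lexical_params,
            fusion_params=FusionParams(**manifest["fusion_params"]),
        )


__all__ = [
    "FusionParams",
    "ScoredCandidate",
    "UnanswerableQueryError",
    "HybridSearchEngine",
    "adaptive_alpha",
    "final_score",
    "aggregate_candidates",
    "rank_candidates",
]
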