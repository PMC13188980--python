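"""Deterministic synthetic corpora, queries, judgments, and test encoders.

Every other module is testable offline against fixtures built here.  A
corpus is generated from a set of :class:`TopicSpec` objects, each carrying
two *disjoint* token vocabularies — the surface vocabulary that documents
are written in, and a paraphrase vocabulary expressing the same topic with
zero lexical overlap — plus a unit base direction in embedding space.
Paraphrase queries emulate the hard retrieval condition where relevant
literature is conceptually related but lexically dissimilar to the query;
exact-term queries emulate keyword search.

Two deterministic encoders implement the encoder contract:

* ``hash`` mode — a text's vector is the sum of pseudo-random unit vectors
  assigned to its tokens, so cosine similarity grows with token overlap
  (a lexically-driven embedding).
* ``topic`` mode — a text maps near its dominant topic's base direction
  (plus a small text-specific perturbation), so same-topic texts have
  cosine >= 0.7 regardless of token overlap while distinct topics stay
  nearly orthogonal (a concept-driven embedding).

All sampling flows from a single integer seed; regeneration is
reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from xml.sax.saxutils import escape

import numpy as np

from .corpus import ArticleRecord, Corpus, normalize_text
from .evaluation import JudgmentSet
from .lexical import tokenize

#: MeSH descriptor prefix that encodes a record's generating topic.
TOPIC_MESH_PREFIX = "SynTopic"

_NOISE_SCALE = 0.3  # topic-mode perturbation; keeps same-topic cosine >= 0.83


def _stable_rng(*parts) -> np.random.Generator:
    """Generator seeded from a SHA-256 of the parts (process-independent)."""
    digest = hashlib.sha256(":".join(str(p) for p in parts).encode("utf-8")).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


@dataclass(frozen=True)
class TopicSpec:
    """One synthetic topic: two disjoint vocabularies and a base direction."""

    topic_id: int
    vocabulary: tuple[str, ...]
    paraphrase_vocabulary: tuple[str, ...]
    base_vector: np.ndarray

    def __post_init__(self) -> None:
        if set(self.vocabulary) & set(self.paraphrase_vocabulary):
            raise ValueError("vocabulary and paraphrase vocabulary must be disjoint")

    @property
    def core_tokens(self) -> tuple[str, ...]:
        """Tokens guaranteed to appear in every document of the topic."""
        return self.vocabulary[:3]

    @property
    def mesh_tag(self) -> str:
        return f"{TOPIC_MESH_PREFIX}{self.topic_id}"


def make_topics(
    n_topics: int, dim: int = 64, seed: int = 0, vocab_size: int = 30
) -> list[TopicSpec]:
    """Build topics with disjoint vocabularies and orthonormal base vectors.

    Base vectors come from a QR decomposition of a seeded Gaussian matrix,
    so pairwise cosines are exactly 0 (< 0.3 as required).
    """
    if n_topics > dim:
        raise ValueError("need dim >= n_topics for orthonormal base vectors")
    rng = _stable_rng(seed, "topics")
    basis, _ = np.linalg.qr(rng.standard_normal((dim, n_topics)))
    topics = []
    for t in range(n_topics):
        vocab = tuple(f"term{t}x{i:02d}" for i in range(vocab_size))
        para = tuple(f"syn{t}x{i:02d}" for i in range(vocab_size))
        topics.append(
            TopicSpec(
                topic_id=t,
                vocabulary=vocab,
                paraphrase_vocabulary=para,
                base_vector=np.ascontiguousarray(basis[:, t]),
            )
        )
    return topics


class SyntheticEncoder:
    """Deterministic test encoder (``hash`` or ``topic`` mode).

    Satisfies the encoder contract: fixed ``dim``, a ``name``, and a
    deterministic ``encode``.  Token-less text encodes to the zero vector
    (callers treat that as un-encodable).
    """

    def __init__(
        self,
        mode: str = "hash",
        dim: int = 64,
        seed: int = 0,
        topics: list[TopicSpec] | None = None,
    ) -> None:
        if mode not in ("hash", "topic"):
            raise ValueError("mode must be 'hash' or 'topic'")
        if mode == "topic" and not topics:
            raise ValueError("topic mode requires topic specs")
        if topics and any(t.base_vector.shape != (dim,) for t in topics):
            raise ValueError("topic base vectors must match encoder dim")
        self.mode = mode
        self.dim = dim
        self.seed = seed
        self.topics = topics or []
        self.name = f"synthetic-{mode}-d{dim}-s{seed}"
        self._token_cache: dict[str, np.ndarray] = {}
        self._topic_lookup: dict[str, TopicSpec] = {}
        for topic in self.topics:
            for tok in topic.vocabulary + topic.paraphrase_vocabulary:
                self._topic_lookup[tok] = topic

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._token_cache.get(token)
        if vec is None:
            raw = _stable_rng(self.seed, "tok", token).standard_normal(self.dim)
            vec = raw / np.linalg.norm(raw)
            self._token_cache[token] = vec
        return vec

    def _hash_encode(self, tokens: list[str]) -> np.ndarray:
        vec = np.zeros(self.dim)
        for tok in tokens:
            vec += self._token_vector(tok)
        return vec

    def _topic_encode(self, tokens: list[str], text: str) -> np.ndarray:
        counts: dict[int, int] = {}
        for tok in tokens:
            topic = self._topic_lookup.get(tok)
            if topic is not None:
                counts[topic.topic_id] = counts.get(topic.topic_id, 0) + 1
        if not counts:
            return self._hash_encode(tokens)
        dominant = min(counts, key=lambda t: (-counts[t], t))
        base = self.topics[dominant].base_vector
        noise = _stable_rng(self.seed, "noise", text).standard_normal(self.dim)
        noise -= np.dot(noise, base) * base  # orthogonal perturbation
        noise /= np.linalg.norm(noise)
        return base + _NOISE_SCALE * noise

    def encode(self, text: str) -> np.ndarray:
        tokens = tokenize(normalize_text(text))
        if not tokens:
            return np.zeros(self.dim)
        if self.mode == "hash":
            return self._hash_encode(tokens)
        return self._topic_encode(tokens, normalize_text(text))


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def generate_corpus(
    n_docs: int,
    topics: list[TopicSpec],
    year_range: tuple[int, int] = (2015, 2024),
    seed: int = 0,
) -> Corpus:
    """Sample a corpus of synthetic records, round-robin over topics.

    Titles contain the topic's core tokens (so exact-term queries built from
    core tokens share a token with every relevant document); abstracts are
    50-200 tokens drawn Zipf-weighted from the topic's surface vocabulary,
    which exercises BM25 term-frequency saturation and length
    normalization.  Years are uniform over ``year_range``; journals,
    authors, and MeSH terms are drawn from small per-topic pools, and every
    record carries its topic's MeSH tag.  Fully reproducible from ``seed``.
    """
    if n_docs < 1 or not topics:
        raise ValueError("need n_docs >= 1 and at least one topic")
    rng = _stable_rng(seed, "corpus")
    records = []
    y_lo, y_hi = year_range
    for i in range(n_docs):
        topic = topics[i % len(topics)]
        vocab = np.array(topic.vocabulary)
        weights = _zipf_weights(len(vocab))
        extra_title = rng.choice(vocab, size=3, p=weights)
        title_tokens = list(topic.core_tokens) + list(extra_title)
        abstract_len = int(rng.integers(50, 201))
        abstract_tokens = rng.choice(vocab, size=abstract_len, p=weights)
        journal = f"Journal of Synthetic Topic {topic.topic_id} No {int(rng.integers(1, 3))}"
        n_auth = int(rng.integers(1, 5))
        authors = tuple(
            f"Author{topic.topic_id}x{int(a)} A"
            for a in rng.choice(6, size=n_auth, replace=False)
        )
        mesh = (topic.mesh_tag,) + tuple(
            f"Mesh{topic.topic_id}x{int(m)}"
            for m in sorted(rng.choice(5, size=int(rng.integers(1, 4)), replace=False))
        )
        doc_id = f"{100000 + i}"
        records.append(
            ArticleRecord(
                doc_id=doc_id,
                title=" ".join(title_tokens).capitalize(),
                abstract=" ".join(abstract_tokens).capitalize() + ".",
                year=int(rng.integers(y_lo, y_hi + 1)),
                journal=journal,
                authors=authors,
                mesh_terms=mesh,
                doi=f"10.0000/synth.{doc_id}" if rng.random() < 0.8 else None,
            )
        )
    return Corpus(records)


@dataclass(frozen=True)
class QueryRecord:
    """One synthetic query with its generating topic and mode."""

    query_id: str
    text: str
    topic_id: int
    paraphrase: bool


def generate_eval_set(
    corpus: Corpus,
    topics: list[TopicSpec],
    n_queries: int,
    paraphrase_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[list[QueryRecord], JudgmentSet]:
    """Build queries and binary judgments over a generated corpus.

    Each query targets one topic; its relevant set is every document
    carrying that topic's MeSH tag.  Exact-term queries are built from the
    topic's core tokens plus sampled surface vocabulary, so they share at
    least one token with every relevant document.  The first
    ``round(paraphrase_fraction * n_queries)`` queries instead use only the
    paraphrase vocabulary, sharing zero tokens with their relevant
    documents.
    """
    if not 0.0 <= paraphrase_fraction <= 1.0:
        raise ValueError("paraphrase_fraction must lie in [0, 1]")
    rng = _stable_rng(seed, "queries")
    by_topic: dict[int, set[str]] = {t.topic_id: set() for t in topics}
    for rec in corpus:
        for topic in topics:
            if topic.mesh_tag in rec.mesh_terms:
                by_topic[topic.topic_id].add(rec.doc_id)
    n_para = round(paraphrase_fraction * n_queries)
    queries = []
    judgments = JudgmentSet()
    for q in range(n_queries):
        topic = topics[q % len(topics)]
        paraphrase = q < n_para
        if paraphrase:
            pool = np.array(topic.paraphrase_vocabulary)
            n_tok = int(rng.integers(4, 9))
            text = " ".join(rng.choice(pool, size=n_tok, replace=False))
        else:
            pool = np.array(topic.vocabulary)
            extra = rng.choice(pool, size=3, p=_zipf_weights(len(pool)))
            text = " ".join(list(topic.core_tokens) + list(extra))
        qid = f"q{q:03d}"
        queries.append(
            QueryRecord(query_id=qid, text=text, topic_id=topic.topic_id,
                        paraphrase=paraphrase)
        )
        judgments.relevant[qid] = set(by_topic[topic.topic_id])
    return queries, judgments


def corpus_to_medline_xml(corpus: Corpus) -> bytes:
    """Render a corpus as PubMed/MEDLINE citation XML (fixture writer).

    Inverse of the corpus reader for the fields both sides carry, so parsing
    round-trips can be exercised without real PubMed data.
    """
    parts = ['<?xml version="1.0" encoding="UTF-8"?>', "<PubmedArticleSet>"]
    for rec in corpus:
        parts.append("<PubmedArticle><MedlineCitation>")
        parts.append(f"<PMID>{escape(rec.doc_id)}</PMID>")
        parts.append("<Article>")
        journal = ""
        if rec.journal:
            journal = f"<Title>{escape(rec.journal)}</Title>"
        year = (
            f"<Year>{rec.year}</Year>" if rec.year is not None else ""
        )
        parts.append(
            f"<Journal>{journal}<JournalIssue><PubDate>{year}</PubDate>"
            "</JournalIssue></Journal>"
        )
        parts.append(f"<ArticleTitle>{escape(rec.title)}</ArticleTitle>")
        if rec.abstract:
            parts.append(
                f"<Abstract><AbstractText>{escape(rec.abstract)}</AbstractText></Abstract>"
            )
        if rec.doi:
            parts.append(f'<ELocationID EIdType="doi">{escape(rec.doi)}</ELocationID>')
        if rec.authors:
            authors = []
            for name in rec.authors:
                last, _, initials = name.rpartition(" ")
                if last:
                    authors.append(
                        f"<Author><LastName>{escape(last)}</LastName>"
                        f"<Initials>{escape(initials)}</Initials></Author>"
                    )
                else:
                    authors.append(
                        f"<Author><LastName>{escape(initials)}</LastName></Author>"
                    )
            parts.append(f"<AuthorList>{''.join(authors)}</AuthorList>")
        parts.append("</Article>")
        if rec.mesh_terms:
            headings = "".join(
                f"<MeshHeading><DescriptorName>{escape(m)}</DescriptorName></MeshHeading>"
                for m in rec.mesh_terms
            )
            parts.append(f"<MeshHeadingList>{headings}</MeshHeadingList>")
        parts.append("</MedlineCitation></PubmedArticle>")
    parts.append("</PubmedArticleSet>")
    return "\n".join(parts).encode("utf-8")


__all__ = [
    "TOPIC_MESH_PREFIX",
    "TopicSpec",
    "SyntheticEncoder",
    "QueryRecord",
    "make_topics",
    "generate_corpus",
    "generate_eval_set",
    "corpus_to_medline_xml",
]
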