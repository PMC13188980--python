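from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pubfuse.corpus import ArticleRecord, Corpus
from pubfuse.synthetic import SyntheticEncoder, make_topics

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


MEDLINE_ONE_ARTICLE = b"""<?xml version="1.0" encoding="UTF-8"?>
<PubmedArticleSet>
  <PubmedArticle><MedlineCitation>
    <PMID>1</PMID>
    <Article>
      <Journal><Title>J Test</Title>
        <JournalIssue><PubDate><Year>2020</Year></PubDate></JournalIssue>
      </Journal>
      <ArticleTitle>T</ArticleTitle>
      <Abstract><AbstractText>A</AbstractText></Abstract>
    </Article>
  </MedlineCitation></PubmedArticle>
</PubmedArticleSet>
"""


@pytest.fixture
def small_corpus() -> Corpus:
    return Corpus(
        [
            ArticleRecord(
                doc_id="10",
                title="Glioma immunotherapy response",
                abstract="Checkpoint blockade in glioma shows variable response.",
                year=2020,
                journal="J One",
                authors=("Smith J", "Chen L"),
                mesh_terms=("Glioma", "Immunotherapy"),
                doi="10.1/abc",
            ),
            ArticleRecord(
                doc_id="11",
                title="Microbiome diversity in soil",
                abstract="Soil bacterial diversity varies with depth and pH.",
                year=2020,
                journal="J Two",
                authors=("Chen L",),
                mesh_terms=("Microbiota", "Soil"),
            ),
            ArticleRecord(
                doc_id="12",
                title="Glioma imaging biomarkers",
                abstract="MRI biomarkers predict glioma progression.",
                year=2021,
                journal="J One",
                authors=("Smith J",),
                mesh_terms=("Glioma", "Magnetic Resonance Imaging"),
            ),
        ]
    )


@pytest.fixture(scope="session")
def topics():
    return make_topics(2, dim=64, seed=0)


@pytest.fixture(scope="session")
def hash_encoder():
    return SyntheticEncoder(mode="hash", dim=64, seed=0)


@pytest.fixture(scope="session")
def topic_encoder(topics):
    return SyntheticEncoder(mode="topic", dim=64, seed=0, topics=topics)


def random_token_corpus(rng: np.random.Generator, n_docs: int, vocab_size: int = 12):
    """Random token lists keyed by doc_id, for brute-force BM25 checks."""
    vocab = [f"w{i}" for i in range(vocab_size)]
    return {
        f"d{j:03d}": list(rng.choice(vocab, size=int(rng.integers(3, 30))))
        for j in range(n_docs)
    }
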