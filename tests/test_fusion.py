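from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pubfuse.corpus import ArticleRecord, Corpus
from pubfuse.fusion import (
    FusionParams,
    HybridSearchEngine,
    ScoredCandidate,
    UnanswerableQueryError,
    adaptive_alpha,
    aggregate_candidates,
    final_score,
    rank_candidates,
)
from pubfuse.lexical import build_shards, lexical_search, tokenize
from pubfuse.semantic import build_vector_store, cosim, semantic_search
from pubfuse.synthetic import SyntheticEncoder, generate_corpus, make_topics


@pytest.fixture(scope="module")
def engine():
    topics = make_topics(2, dim=64, seed=0)
    corpus = generate_corpus(60, topics, seed=0)
    encoder = SyntheticEncoder(mode="hash", dim=64, seed=0)
    return HybridSearchEngine.build(corpus, encoder, fusion_params=FusionParams(tau=0.0))


class TestAdaptiveAlpha:
    def test_midpoint_is_exactly_half(self):
        assert adaptive_alpha(0.5) == 0.5

    def test_hand_values_at_extremes(self):
        assert adaptive_alpha(1.0) == pytest.approx(1.0 / (1.0 + math.exp(-5.0)), abs=1e-10)
        assert adaptive_alpha(1.0) == pytest.approx(0.99331, abs=5e-6)
        assert adaptive_alpha(0.0) == pytest.approx(0.00669, abs=5e-6)

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    def test_strictly_increasing(self, x1, x2):
        # strictness is asserted only above floating-point resolution
        if x1 + 1e-9 < x2:
            assert adaptive_alpha(x1) < adaptive_alpha(x2)

    def test_sharpness_limits(self):
        steep = FusionParams(a_sharp=1e3)
        assert adaptive_alpha(0.4, steep) < 1e-10
        assert adaptive_alpha(0.6, steep) > 1.0 - 1e-10

    def test_override_fixes_alpha(self):
        params = FusionParams(alpha_override=1.0)
        assert adaptive_alpha(0.0, params) == 1.0


class TestFinalScore:
    def test_equal_components_are_alpha_independent(self):
        assert final_score(0.5, 0.5) == pytest.approx(0.5)

    def test_lexical_dominant_regime(self):
        assert final_score(1.0, 0.0) == pytest.approx(0.99331, abs=5e-6)

    def test_semantic_dominant_regime(self):
        assert final_score(0.0, 1.0) == pytest.approx(0.99331, abs=5e-6)

    def test_out_of_range_inputs_raise(self):
        with pytest.raises(ValueError):
            final_score(1.2, 0.5)
        with pytest.raises(ValueError):
            final_score(0.5, -0.1)

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    def test_bounded_by_arguments(self, lex, sem):
        fs = final_score(lex, sem)
        assert min(lex, sem) - 1e-12 <= fs <= max(lex, sem) + 1e-12

    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
    )
    def test_strictly_increasing_in_cosim(self, lex, s1, s2):
        if s1 + 1e-9 < s2:
            assert final_score(lex, s1) < final_score(lex, s2)


class TestAggregateCandidates:
    @pytest.fixture
    def setup(self):
        corpus = Corpus(
            [
                ArticleRecord(doc_id="1", title="alpha beta gamma", year=2020),
                ArticleRecord(doc_id="2", title="alpha delta", year=2020),
                ArticleRecord(doc_id="3", title="epsilon zeta", year=2021),
            ]
        )
        encoder = SyntheticEncoder(mode="hash", dim=64, seed=0)
        shards = build_shards(corpus)
        store = build_vector_store(corpus, encoder)
        return corpus, encoder, shards, store

    def test_doc_in_both_lists_appears_once(self, setup):
        corpus, encoder, shards, store = setup
        tokens = tokenize("alpha")
        qvec = encoder.encode("alpha")
        lex = lexical_search(tokens, shards, 10)
        sem = semantic_search(qvec, store, 0.0, 10)
        pool = aggregate_candidates(lex, sem, shards, store, tokens, qvec, corpus)
        ids = [c.doc_id for c in pool]
        assert len(ids) == len(set(ids))
        assert set(d for d, _ in lex) | set(d for d, _ in sem) == set(ids)

    def test_semantic_only_doc_gets_zero_lexical_and_semantic_weighting(self, setup):
        corpus, encoder, shards, store = setup
        # query shares no token with doc 3, but we inject it as a semantic hit
        tokens = tokenize("alpha")
        qvec = encoder.encode("alpha")
        doc3_cos = cosim(qvec, store.get("3"))
        lex = lexical_search(tokens, shards, 10)
        pool = aggregate_candidates(
            lex, [("3", doc3_cos)], shards, store, tokens, qvec, corpus
        )
        cand = {c.doc_id: c for c in pool}["3"]
        assert cand.raw_bm25 == 0.0
        assert cand.bm2501 == 0.0
        expected_alpha = adaptive_alpha(0.0)
        assert cand.fs == pytest.approx(
            expected_alpha * 0.0 + (1 - expected_alpha) * doc3_cos
        )

    def test_empty_semantic_hits_pool_equals_lexical(self, setup):
        corpus, encoder, shards, store = setup
        tokens = tokenize("alpha")
        lex = lexical_search(tokens, shards, 10)
        pool = aggregate_candidates(lex, [], shards, store, tokens, None, corpus)
        assert {c.doc_id for c in pool} == {d for d, _ in lex}

    def test_candidate_absent_from_corpus_raises(self, setup):
        corpus, encoder, shards, store = setup
        with pytest.raises(KeyError):
            aggregate_candidates(
                [("missing", 1.0)], [], shards, store, ["alpha"], None, corpus
            )

    def test_fs_invariant_holds_for_every_candidate(self, setup):
        corpus, encoder, shards, store = setup
        tokens = tokenize("alpha epsilon")
        qvec = encoder.encode("alpha epsilon")
        lex = lexical_search(tokens, shards, 10)
        sem = semantic_search(qvec, store, 0.0, 10)
        for c in aggregate_candidates(lex, sem, shards, store, tokens, qvec, corpus):
            assert c.fs == pytest.approx(c.alpha * c.bm2501 + (1 - c.alpha) * c.cosim)
            assert c.alpha == pytest.approx(adaptive_alpha(c.bm2501))


def _cand(doc_id, fs, lex=0.0):
    return ScoredCandidate(
        doc_id=doc_id, raw_bm25=lex, bm2501=lex, cosim=0.0, alpha=0.5, fs=fs
    )


class TestRankCandidates:
    def test_strict_threshold(self):
        pool = [_cand("a", 0.9), _cand("b", 0.6), _cand("c", 0.3), _cand("d", 0.5)]
        out = rank_candidates(pool, tau=0.5)
        assert [c.doc_id for c in out] == ["a", "b"]

    def test_fs_tie_broken_by_higher_lexical_score(self):
        pool = [_cand("x", 0.7, lex=0.2), _cand("y", 0.7, lex=0.8)]
        out = rank_candidates(pool, tau=0.0)
        assert [c.doc_id for c in out] == ["y", "x"]

    def test_remaining_tie_lexicographic(self):
        pool = [_cand("b", 0.7, lex=0.5), _cand("a", 0.7, lex=0.5)]
        assert [c.doc_id for c in rank_candidates(pool, tau=0.0)] == ["a", "b"]

    def test_tau_one_returns_empty(self):
        pool = [_cand("a", 1.0)]
        assert rank_candidates(pool, tau=1.0) == []


class TestRetrieve:
    def test_threshold_nesting_over_queries(self, engine):
        topics = make_topics(2, dim=64, seed=0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            topic = topics[int(rng.integers(0, 2))]
            n = int(rng.integers(1, 5))
            query = " ".join(rng.choice(np.array(topic.vocabulary), size=n))
            prev = None
            for tau in (0.0, 0.2, 0.4, 0.6, 0.8):
                ids = {
                    c.doc_id
                    for c in engine.retrieve(query, replace(engine.fusion_params, tau=tau))
                }
                if prev is not None:
                    assert ids <= prev
                prev = ids

    def test_determinism_across_thread_schedules(self, engine):
        query = "term0x00 term0x03 term1x02"
        runs = [engine.retrieve(query, n_jobs=j) for j in (1, 2, 4, 1)]
        assert all(r == runs[0] for r in runs[1:])

    def test_unanswerable_query_raises(self, engine):
        with pytest.raises(UnanswerableQueryError):
            engine.retrieve("!!! ???")

    def test_reduction_limit_alpha_one_is_pure_lexical(self, engine):
        rng = np.random.default_rng(1)
        topics = make_topics(2, dim=64, seed=0)
        for _ in range(10):
            topic = topics[int(rng.integers(0, 2))]
            query = " ".join(rng.choice(np.array(topic.vocabulary), size=3))
            params = replace(engine.fusion_params, alpha_override=1.0, tau=0.0)
            got = engine.retrieve(query, params)
            pool = engine.score_pool(query, params)
            want = sorted(pool, key=lambda c: (-c.bm2501, c.doc_id))
            want = [c for c in want if c.fs > 0.0]
            assert [c.doc_id for c in got] == [c.doc_id for c in want]

    def test_reduction_limit_alpha_zero_is_pure_semantic(self, engine):
        rng = np.random.default_rng(2)
        topics = make_topics(2, dim=64, seed=0)
        for _ in range(10):
            topic = topics[int(rng.integers(0, 2))]
            query = " ".join(rng.choice(np.array(topic.vocabulary), size=3))
            params = replace(engine.fusion_params, alpha_override=0.0, tau=0.0)
            got = engine.retrieve(query, params)
            pool = engine.score_pool(query, params)
            want = [c for c in pool if c.fs > 0.0]
            want.sort(key=lambda c: (-c.cosim, -c.bm2501, c.doc_id))
            assert [c.doc_id for c in got] == [c.doc_id for c in want]

    def test_hybrid_rescue_of_lexically_dissimilar_relevant_doc(self):
        """A conceptually matching doc with zero token overlap must outrank a
        one-token distractor with low semantic similarity."""
        corpus = Corpus(
            [
                ArticleRecord(doc_id="rel", title="heart attack outcomes", year=2020),
                ArticleRecord(doc_id="dis", title="infarction of unrelated tissue", year=2020),
                ArticleRecord(doc_id="full", title="myocardial infarction therapy", year=2020),
            ]
        )

        class FixtureEncoder:
            dim = 2
            name = "fixture"

            def encode(self, text):
                # query and 'rel' share a direction (cos 0.9 by construction);
                # 'dis' is nearly orthogonal (cos 0.1)
                if "myocardial" in text:  # the query and its exact match
                    return np.array([1.0, 0.0])
                if "heart" in text:
                    return np.array([0.9, math.sqrt(1 - 0.81)])
                return np.array([0.1, math.sqrt(1 - 0.01)])

        engine = HybridSearchEngine.build(
            corpus, FixtureEncoder(), fusion_params=FusionParams(tau=0.0)
        )
        results = engine.retrieve("myocardial infarction therapy")
        ids = [c.doc_id for c in results]
        assert ids.index("rel") < ids.index("dis")


class TestSimilarArticles:
    def test_duplicate_record_ranks_first_with_cosine_one(self, topics):
        corpus = generate_corpus(10, topics, seed=1)
        rec = next(iter(corpus))
        dup = ArticleRecord(
            doc_id="dup", title=rec.title, abstract=rec.abstract, year=rec.year
        )
        corpus.add(dup)
        encoder = SyntheticEncoder(mode="hash", dim=64, seed=0)
        engine = HybridSearchEngine.build(corpus, encoder)
        hits = engine.similar_articles(rec.doc_id, k=3)
        assert hits[0][0] == "dup"
        assert hits[0][1] == pytest.approx(1.0)

    def test_matches_brute_force_and_excludes_self(self, engine):
        ref = engine.corpus.doc_ids()[0]
        hits = engine.similar_articles(ref, k=1000)
        assert ref not in {d for d, _ in hits}
        assert len(hits) == len(engine.corpus) - 1
        brute = sorted(
            (
                (d, cosim(engine.store.get(ref), engine.store.get(d)))
                for d in engine.corpus.doc_ids()
                if d != ref
            ),
            key=lambda h: (-h[1], h[0]),
        )
        assert [d for d, _ in hits] == [d for d, _ in brute]

    def test_unknown_doc_id_raises(self, engine):
        with pytest.raises(KeyError):
            engine.similar_articles("nope")


class TestEnginePersistence:
    def test_save_load_round_trip_preserves_retrieval(self, engine, tmp_path):
        engine.save(tmp_path / "state")
        loaded = HybridSearchEngine.load(tmp_path / "state", engine.encoder)
        query = "term0x00 term0x05"
        assert loaded.retrieve(query) == engine.retrieve(query)

    def test_encoder_mismatch_rejected(self, engine, tmp_path):
        engine.save(tmp_path / "state")
        other = SyntheticEncoder(mode="hash", dim=32, seed=0)
        with pytest.raises(ValueError, match="encoder mismatch"):
            HybridSearchEngine.load(tmp_path / "state", other)
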