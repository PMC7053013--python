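import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biomedqa.gazetteer import EntityMention
from biomedqa.question import analyze_question
from biomedqa.ranking import (
    AnswerCandidate,
    extract_terms,
    filter_by_focus_type,
    match_definition_patterns,
    rank_candidates,
    segment_sentences,
    wrwmd_similarity,
)
from biomedqa.retrieval import DocumentRecord

from conftest import make_embeddings, make_lexicon, random_embeddings
from oracles import full_wmd_lp, relaxed_wmd_lp


class TestSegmentation:
    def test_title_is_sentence_zero(self):
        doc = DocumentRecord(
            "d0", "A title here.",
            "First sentence about results. Second sentence follows. Third closes.",
        )
        sents = segment_sentences(doc)
        assert len(sents) == 4
        assert sents[0] == "A title here."

    def test_abbreviation_does_not_split(self):
        doc = DocumentRecord("d0", "", "Drugs, e.g. aspirin, help. Fever drops.")
        assert len(segment_sentences(doc)) == 2

    def test_empty_abstract_leaves_title_only(self):
        doc = DocumentRecord("d0", "Only a title.", "")
        assert segment_sentences(doc) == ["Only a title."]


class TestWrwmd:
    def test_superset_answer_scores_one(self):
        emb = random_embeddings(["a", "b", "c", "d"], 6, np.random.default_rng(0))
        q = {"a": 1.0, "b": 2.0}
        assert wrwmd_similarity(q, ["a", "b", "c", "d"], emb) == pytest.approx(1.0)

    def test_orthogonal_terms_score_zero(self):
        emb = make_embeddings({"a": [1, 0], "b": [0, 1], "x": [0, 1], "y": [0, 1]})
        assert wrwmd_similarity({"a": 1.0}, ["x", "y"], emb) == pytest.approx(0.0)

    def test_hand_computed_weighted_mean(self):
        # maxcos(a)=0.9 to x, maxcos(b)=0.3 to y → (2·0.9 + 1·0.3)/3 = 0.7
        ca, sa = 0.9, np.sqrt(1 - 0.9**2)
        cb, sb = 0.3, np.sqrt(1 - 0.3**2)
        emb = make_embeddings(
            {
                "a": [1, 0, 0],
                "b": [0, 0, 1],
                "x": [ca, sa, 0],
                "y": [0, sb, cb],
            }
        )
        got = wrwmd_similarity({"a": 2.0, "b": 1.0}, ["x", "y"], emb)
        # x vs b: cos = 0; y vs a: 0 → maxima are as constructed
        assert got == pytest.approx(0.7, abs=1e-9)

    def test_equals_relaxed_lp_optimum(self):
        rng = np.random.default_rng(7)
        surfaces = [f"w{i}" for i in range(12)]
        emb = random_embeddings(surfaces, 8, rng)
        q = {s: float(rng.uniform(0.1, 3.0)) for s in surfaces[:5]}
        a = surfaces[4:10]
        ours = wrwmd_similarity(q, a, emb)
        assert ours == pytest.approx(relaxed_wmd_lp(q, a, emb), abs=1e-9)

    def test_relaxation_lower_bounds_full_transport(self):
        # on a shared cost matrix the one-constraint optimum bounds the full one
        rng = np.random.default_rng(3)
        n, m = 4, 5
        cost = rng.uniform(0.1, 2.0, (n, m))
        d = rng.dirichlet(np.ones(n))
        d_prime = rng.dirichlet(np.ones(m))
        full_cost, T = full_wmd_lp(d, d_prime, cost)
        relaxed_cost = float(np.sum(d * cost.min(axis=1)))
        assert relaxed_cost <= full_cost + 1e-9
        np.testing.assert_allclose(T.sum(axis=1), d, atol=1e-8)
        np.testing.assert_allclose(T.sum(axis=0), d_prime, atol=1e-8)

    def test_duplicate_answer_terms_do_not_change_score(self):
        emb = random_embeddings(["a", "x", "y"], 4, np.random.default_rng(1))
        q = {"a": 1.0}
        once = wrwmd_similarity(q, ["x", "y"], emb)
        thrice = wrwmd_similarity(q, ["x", "x", "x", "y", "y"], emb)
        assert once == pytest.approx(thrice)

    def test_irrelevant_orthogonal_term_leaves_score_unchanged(self):
        emb = make_embeddings(
            {"a": [1, 0, 0], "x": [0.8, 0.6, 0], "noise": [0, 0, 1]}
        )
        q = {"a": 1.0}
        assert wrwmd_similarity(q, ["x"], emb) == pytest.approx(
            wrwmd_similarity(q, ["x", "noise"], emb)
        )

    def test_oov_question_term_scores_by_exact_match(self):
        emb = make_embeddings({"x": [1.0, 0.0]})
        assert wrwmd_similarity({"zorblatt": 2.0}, ["zorblatt", "x"], emb) == 1.0
        assert wrwmd_similarity({"zorblatt": 2.0}, ["x"], emb) == 0.0

    def test_empty_answer_scores_zero(self):
        emb = make_embeddings({"a": [1.0]})
        assert wrwmd_similarity({"a": 1.0}, [], emb) == 0.0

    def test_score_bounded_in_unit_interval(self):
        rng = np.random.default_rng(5)
        emb = random_embeddings([f"t{i}" for i in range(10)], 4, rng)
        for _ in range(20):
            qn = rng.integers(1, 5)
            an = rng.integers(1, 6)
            q = {f"t{i}": float(rng.uniform(0.1, 2)) for i in rng.choice(10, qn, replace=False)}
            a = [f"t{i}" for i in rng.choice(10, an, replace=False)]
            s = wrwmd_similarity(q, a, emb)
            assert -1.0 - 1e-12 <= s <= 1.0 + 1e-12


class TestRanking:
    def setup_method(self):
        self.lex = make_lexicon({"alemtuzumab": 3.0, "leukemia": 2.0, "treats": 1.0})
        rng = np.random.default_rng(2)
        self.emb = random_embeddings(
            ["alemtuzumab", "leukemia", "treats", "unrelated", "words", "appear"],
            8, rng,
        )

    def test_question_duplicate_ranks_first_with_score_one(self):
        q = analyze_question("Which drug treats leukemia?")
        docs = [
            DocumentRecord("d0", "", "Unrelated words appear."),
            DocumentRecord("d1", "", "Which drug treats leukemia."),
        ]
        lex = make_lexicon({"drug": 1.0, "treats": 1.0, "leukemia": 2.0})
        emb = random_embeddings(["drug", "treats", "leukemia", "unrelated", "words", "appear"], 6, np.random.default_rng(0))
        cands = rank_candidates(q, docs, lex, emb)
        assert cands[0].doc_id == "d1"
        assert cands[0].wrwmd_score == pytest.approx(1.0)

    def test_equal_scores_preserve_document_order(self):
        q = analyze_question("Which drug treats leukemia?")
        docs = [
            DocumentRecord("a", "", "Same sentence text."),
            DocumentRecord("b", "", "Same sentence text."),
        ]
        lex = make_lexicon({"drug": 1.0})
        emb = make_embeddings({"drug": [1.0, 0.0]})
        cands = rank_candidates(q, docs, lex, emb)
        assert [c.doc_id for c in cands] == ["a", "b"]

    def test_order_matches_brute_force_scoring(self):
        rng = np.random.default_rng(4)
        vocab = [f"v{i}" for i in range(15)]
        emb = random_embeddings(vocab + ["drug", "treats", "leukemia"], 6, rng)
        lex = make_lexicon({s: 1.0 for s in vocab})
        docs = [
            DocumentRecord(f"d{i}", "", " ".join(rng.choice(vocab, 6)) + ".")
            for i in range(10)
        ]
        q = analyze_question("Which drug treats leukemia?")
        cands = rank_candidates(q, docs, lex, emb)
        scores = [c.wrwmd_score for c in cands]
        assert scores == sorted(scores, reverse=True)
        # every sentence present exactly once
        assert len(cands) == sum(len(segment_sentences(d)) for d in docs)


class TestFilters:
    def make_cands(self):
        drug = EntityMention("alemtuzumab", "drug", 0, 1, 0)
        return [
            AnswerCandidate("Alemtuzumab works.", "d0", 0, 0.9, entities=[drug]),
            AnswerCandidate("Nothing here.", "d1", 0, 0.8, entities=[]),
        ]

    def test_focus_type_filter_keeps_matching_only(self):
        cands = self.make_cands()
        kept = filter_by_focus_type(cands, "drug")
        assert [c.doc_id for c in kept] == ["d0"]

    def test_no_match_returns_empty_for_caller_fallback(self):
        kept = filter_by_focus_type(self.make_cands(), "organism")
        assert kept == []

    def test_definition_pattern_promotes_over_similarity(self):
        cands = [
            AnswerCandidate("Unrelated but high scoring.", "d0", 0, 0.95),
            AnswerCandidate(
                "LHCII is the most abundant membrane protein on earth.", "d1", 0, 0.2
            ),
        ]
        out = match_definition_patterns("LHCII", cands)
        assert out[0].doc_id == "d1"

    def test_no_pattern_hit_keeps_order(self):
        cands = [
            AnswerCandidate("First.", "d0", 0, 0.9),
            AnswerCandidate("Second.", "d1", 0, 0.8),
        ]
        assert [c.doc_id for c in match_definition_patterns("LHCII", cands)] == [
            "d0", "d1",
        ]

    def test_two_tier_order_within_groups(self):
        cands = [
            AnswerCandidate("No hit, top score.", "d0", 0, 0.9),
            AnswerCandidate("X is a kinase.", "d1", 0, 0.5),
            AnswerCandidate("No hit, mid score.", "d2", 0, 0.7),
            AnswerCandidate("X is defined as a kinase.", "d3", 0, 0.1),
        ]
        out = match_definition_patterns("X", cands)
        assert [c.doc_id for c in out] == ["d1", "d3", "d0", "d2"]


def test_extract_terms_merges_vocabulary_phrases():
    lex = make_lexicon({"remission induction": 2.0, "remission": 1.0})
    terms = extract_terms("remission induction failed", lex)
    assert "remission induction" in terms
    assert "remission" not in terms  # swallowed by the phrase
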