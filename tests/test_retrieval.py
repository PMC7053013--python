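import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biomedqa.annotation import load_nominalizations
from biomedqa.gazetteer import EntityMention
from biomedqa.question import analyze_question, generate_candidate_terms
from biomedqa.retrieval import (
    DocumentRecord,
    InMemoryIndex,
    KeywordQuery,
    SearchConstruct,
    build_query,
    construct_weight,
    evaluate_boolean,
    iterative_retrieve,
)

from conftest import make_lexicon
from oracles import brute_force_boolean, simulate_drop_order


class TestConstructWeight:
    def test_single_in_vocab_term(self):
        lex = make_lexicon({"alpha": 0.5})
        st_ = SearchConstruct([("alpha", 0.5)], "np")
        assert construct_weight(st_, lex) == pytest.approx(0.5)

    def test_oov_phrase_contributes_min_token_weight(self):
        lex = make_lexicon({"alpha": 0.6, "low": 0.2, "high": 0.9})
        st_ = SearchConstruct([("alpha", 0.6), ("low high", 0.0)], "np")
        # (0.6 + min(0.2, 0.9)) / 2
        assert construct_weight(st_, lex) == pytest.approx(0.4)

    def test_all_oov_zero_tokens_floor_at_zero(self):
        lex = make_lexicon({"unrelated": 1.0})
        st_ = SearchConstruct([("foo bar", 0.0), ("baz", 0.0)], "np")
        assert construct_weight(st_, lex) == 0.0

    def test_empty_construct_is_an_error(self):
        lex = make_lexicon({"x": 1.0})
        with pytest.raises(ValueError):
            construct_weight(SearchConstruct([], "np"), lex)

    def test_hand_computed_table(self):
        lex = make_lexicon({"a": 1.0, "b": 2.0, "c": 0.25, "d": 3.0})
        cases = [
            ([("a", 1.0)], 1.0),
            ([("a", 1.0), ("b", 2.0)], 1.5),
            ([("b", 2.0), ("c d", 0.0)], (2.0 + 0.25) / 2),
            ([("a c", 0.0), ("b d", 0.0)], (0.25 + 2.0) / 2),
            ([("a", 1.0), ("b", 2.0), ("d", 3.0)], 2.0),
        ]
        for disjuncts, expected in cases:
            got = construct_weight(SearchConstruct(list(disjuncts), "np"), lex)
            assert got == pytest.approx(expected, abs=1e-12)


FIG2_QUESTION = (
    "Is alemtuzumab effective for remission induction in patients "
    "diagnosed with T-cell prolymphocytic leukemia?"
)


@pytest.fixture()
def fig2_query():
    lex = make_lexicon(
        {
            "alemtuzumab": 4.0,
            "remission induction": 3.5,
            "remission": 2.0,
            "induction": 1.8,
            "patients": 0.5,
            "t-cell prolymphocytic leukemia": 4.2,
            "prolymphocytic leukemia": 3.9,
            "leukemia": 2.5,
            "diagnose": 1.2,
            "diagnosed": 1.1,
            "diagnosis": 1.3,
        }
    )
    q = analyze_question(FIG2_QUESTION)
    terms = generate_candidate_terms(q, lex, load_nominalizations())
    entities = [EntityMention("alemtuzumab", "drug", 1, 2, 0)]
    return build_query(terms, entities, lex), lex


class TestBuildQuery:
    def test_entity_construct_is_protected(self, fig2_query):
        query, _ = fig2_query
        prot = [c for c in query.constructs if c.protected]
        assert any("alemtuzumab" in c.surfaces() for c in prot)

    def test_verb_construct_includes_conjugations_and_nominalization(self, fig2_query):
        query, _ = fig2_query
        verb = [c for c in query.constructs if c.kind == "verb"]
        assert len(verb) == 1
        surfaces = set(verb[0].surfaces())
        assert {"diagnose", "diagnosed", "diagnosis"} <= surfaces

    def test_disjuncts_sorted_descending_by_weight(self, fig2_query):
        query, _ = fig2_query
        for c in query.constructs:
            weights = [w for _, w in c.disjuncts]
            assert weights == sorted(weights, reverse=True)

    def test_single_np_question_yields_np_construct(self):
        lex = make_lexicon({"leukemia": 2.0})
        q = analyze_question("What is leukemia?")
        query = build_query(generate_candidate_terms(q, lex), [], lex)
        kinds = {c.kind for c in query.constructs}
        assert "np" in kinds and "verb" not in kinds

    def test_empty_candidates_error(self):
        lex = make_lexicon({"x": 1.0})
        with pytest.raises(ValueError):
            build_query([], [], lex)


def make_docs(texts):
    return [DocumentRecord(f"d{i}", "", t) for i, t in enumerate(texts)]


class TestBooleanEvaluation:
    def test_single_term_counts_matching_docs(self):
        docs = make_docs(["x y", "x z", "w", "q x", "z"])
        idx = InMemoryIndex(docs)
        query = KeywordQuery([SearchConstruct([("x", 1.0)], "word")])
        res = evaluate_boolean(query, idx)
        assert res.total_hits == 3

    def test_and_semantics_with_disjoint_sets(self):
        docs = make_docs(["x", "y"])
        idx = InMemoryIndex(docs)
        query = KeywordQuery(
            [
                SearchConstruct([("x", 1.0)], "word"),
                SearchConstruct([("y", 1.0)], "word"),
            ]
        )
        assert evaluate_boolean(query, idx).total_hits == 0

    def test_phrase_requires_contiguity(self):
        docs = make_docs(["remission induction therapy", "induction of remission"])
        idx = InMemoryIndex(docs)
        query = KeywordQuery([SearchConstruct([("remission induction", 1.0)], "np")])
        res = evaluate_boolean(query, idx)
        assert res.ids == ["d0"]
        assert res.total_hits == 1

    def test_total_hits_exact_when_ids_capped(self):
        docs = make_docs(["x"] * 7)
        idx = InMemoryIndex(docs)
        query = KeywordQuery([SearchConstruct([("x", 1.0)], "word")])
        res = evaluate_boolean(query, idx, max_hits=3)
        assert len(res.ids) == 3 and res.total_hits == 7

    def test_empty_query_is_an_error(self):
        idx = InMemoryIndex(make_docs(["x"]))
        with pytest.raises(ValueError):
            evaluate_boolean(KeywordQuery([]), idx)

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_matches_brute_force_scan(self, data):
        vocab = ["aa", "bb", "cc", "dd", "ee"]
        docs = make_docs(
            data.draw(
                st.lists(
                    st.lists(st.sampled_from(vocab), min_size=1, max_size=10).map(" ".join),
                    min_size=1,
                    max_size=15,
                )
            )
        )
        n_constructs = data.draw(st.integers(1, 3))
        constructs = []
        for _ in range(n_constructs):
            n_disj = data.draw(st.integers(1, 3))
            disjuncts = []
            for _ in range(n_disj):
                n_tok = data.draw(st.integers(1, 2))
                surface = " ".join(data.draw(st.sampled_from(vocab)) for _ in range(n_tok))
                disjuncts.append((surface, 1.0))
            constructs.append(SearchConstruct(disjuncts, "np"))
        idx = InMemoryIndex(docs)
        res = evaluate_boolean(KeywordQuery(constructs), idx)
        assert set(res.ids) == brute_force_boolean(docs, constructs)

    @settings(deadline=None, max_examples=40)
    @given(st.data())
    def test_removing_a_construct_never_shrinks_results(self, data):
        vocab = ["aa", "bb", "cc"]
        docs = make_docs(
            data.draw(
                st.lists(
                    st.lists(st.sampled_from(vocab), min_size=1, max_size=6).map(" ".join),
                    min_size=1, max_size=10,
                )
            )
        )
        surfaces = data.draw(st.lists(st.sampled_from(vocab), min_size=2, max_size=4))
        constructs = [SearchConstruct([(s, 1.0)], "word") for s in surfaces]
        idx = InMemoryIndex(docs)
        full = set(evaluate_boolean(KeywordQuery(list(constructs)), idx).ids)
        reduced = set(
            evaluate_boolean(KeywordQuery(list(constructs[:-1])), idx).ids
        )
        assert full <= reduced


class TestIterativeRelaxation:
    def test_no_relaxation_when_initial_query_hits(self):
        docs = make_docs(["x y"] * 5)
        idx = InMemoryIndex(docs)
        lex = make_lexicon({"x": 1.0, "y": 0.5})
        query = KeywordQuery(
            [
                SearchConstruct([("x", 1.0)], "word", weight=1.0, origin=0),
                SearchConstruct([("y", 0.5)], "word", weight=0.5, origin=1),
            ]
        )
        res, final = iterative_retrieve(query, idx, lex)
        assert res.total_hits == 5
        assert final.iteration == 0 and final.history == []

    def test_verb_construct_dropped_before_heavier_groups(self):
        # the verb never matches; dropping it (first, despite high weight)
        # lets the np construct match
        docs = make_docs(["leukemia case report"])
        idx = InMemoryIndex(docs)
        lex = make_lexicon({"leukemia": 0.5, "diagnose": 3.0})
        query = KeywordQuery(
            [
                SearchConstruct([("diagnose", 3.0)], "verb", weight=3.0, origin=0),
                SearchConstruct([("leukemia", 0.5)], "np", weight=0.5, origin=1),
            ]
        )
        res, final = iterative_retrieve(query, idx, lex)
        assert res.total_hits == 1
        assert final.history[0] == ("diagnose", 0)

    def test_protected_entity_survives_relaxation(self, fig2_query):
        query, lex = fig2_query
        # corpus where only "alemtuzumab" appears: every other construct
        # must be dropped; the protected one is dropped last (never here)
        docs = make_docs(["alemtuzumab infusion outcome", "unrelated text"])
        idx = InMemoryIndex(docs)
        res, final = iterative_retrieve(query, idx, lex)
        assert res.ids == ["d0"]
        remaining = {s for c in final.constructs for s in c.surfaces()}
        assert "alemtuzumab" in remaining
        dropped = {s for s, _ in final.history}
        assert "alemtuzumab" not in dropped

    def test_protected_absent_from_history_until_others_are_singletons(self, fig2_query):
        query, lex = fig2_query
        original = copy.deepcopy(query)
        idx = InMemoryIndex(make_docs(["nothing matches here"]))
        res, final = iterative_retrieve(query, idx, lex)
        assert res.exhausted
        # replay: at the time of each protected drop all other constructs
        # must already be singletons or gone
        protected_origins = {c.origin for c in original.constructs if c.protected}
        state = {c.origin: len(c.disjuncts) for c in original.constructs}
        for surface, origin in final.history:
            if origin in protected_origins:
                assert all(
                    n <= 1 for o, n in state.items() if o not in protected_origins
                )
            state[origin] -= 1

    def test_drop_sequence_matches_policy_simulator(self, fig2_query):
        query, lex = fig2_query
        sim_order = simulate_drop_order(query)
        idx = InMemoryIndex(make_docs(["zzz"]))  # nothing ever matches
        res, final = iterative_retrieve(copy.deepcopy(query), idx, lex)
        assert res.exhausted
        assert final.history == sim_order

    def test_determinism_and_history_length(self, fig2_query):
        query, lex = fig2_query
        idx = InMemoryIndex(make_docs(["alemtuzumab only", "noise"]))
        r1, f1 = iterative_retrieve(copy.deepcopy(query), idx, lex)
        r2, f2 = iterative_retrieve(copy.deepcopy(query), idx, lex)
        assert r1.ids == r2.ids
        assert f1.history == f2.history
        assert f1.iteration == len(f1.history)

    def test_exhaustion_flag_when_nothing_matches(self):
        idx = InMemoryIndex(make_docs(["zzz"]))
        lex = make_lexicon({"absent": 1.0})
        query = KeywordQuery([SearchConstruct([("absent", 1.0)], "np", weight=1.0)])
        res, final = iterative_retrieve(query, idx, lex)
        assert res.exhausted and res.ids == []

    def test_oversized_first_hit_is_truncated_not_rejected(self):
        docs = make_docs(["x common"] * 30)
        idx = InMemoryIndex(docs)
        lex = make_lexicon({"x": 1.0})
        query = KeywordQuery([SearchConstruct([("x", 1.0)], "word", weight=1.0)])
        res, _ = iterative_retrieve(query, idx, lex, max_hits=10)
        assert res.total_hits == 30 and len(res.ids) == 10
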