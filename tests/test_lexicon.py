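import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from biomedqa.lexicon import (
    Lexicon,
    VocabEntry,
    _llr_2x2,
    build_document_frequencies,
    cosine_similarity,
    load_embeddings,
    mine_phrases,
    tokenize_simple,
)


class TestPhraseMining:
    def test_strong_collocation_is_detected(self):
        # "t cell" in 50 of 100 docs; the parts never occur apart
        docs = [["t", "cell", "response"] for _ in range(50)]
        docs += [["antibody", "titer", "assay"] for _ in range(50)]
        phrases = mine_phrases(docs, min_count=5, threshold=30.0)
        assert "t cell" in phrases

    def test_llr_statistic_matches_gtest(self):
        # same 2x2 table scored by scipy's log-likelihood G-test
        table = [[50, 3], [7, 940]]
        g, _, _, _ = chi2_contingency(table, lambda_="log-likelihood", correction=False)
        assert _llr_2x2(50, 3, 7, 940) == pytest.approx(g, abs=1e-9)

    def test_independent_shuffled_corpus_yields_nothing(self):
        rng = np.random.default_rng(0)
        vocab = [f"w{i}" for i in range(30)]
        docs = [list(rng.choice(vocab, size=20)) for _ in range(200)]
        assert mine_phrases(docs, min_count=5, threshold=30.0) == set()

    def test_count_floor_excludes_rare_ngrams(self):
        docs = [["alpha", "beta"]] * 4 + [["gamma", "delta", "x"]] * 50
        assert "alpha beta" not in mine_phrases(docs, min_count=5, threshold=1.0)

    def test_invariant_to_document_order(self):
        rng = np.random.default_rng(1)
        docs = [["t", "cell"]] * 20 + [list(rng.choice(["a", "b", "c"], 5)) for _ in range(30)]
        fwd = mine_phrases(docs, min_count=5, threshold=10.0)
        rev = mine_phrases(docs[::-1], min_count=5, threshold=10.0)
        assert fwd == rev

    def test_empty_corpus_is_an_error(self):
        with pytest.raises(ValueError):
            mine_phrases([], min_count=5, threshold=10.0)

    def test_trigram_phrases_grow_from_accepted_bigrams(self):
        docs = [["t", "cell", "receptor", "assay"]] * 30 + [["x", "y"]] * 30
        phrases = mine_phrases(docs, min_count=5, threshold=10.0)
        assert "t cell receptor" in phrases


class TestDocumentFrequencies:
    def make_corpus(self):
        return [
            {"id": str(i), "title": f"doc {i}", "abstract": "shared term here"}
            for i in range(10)
        ]

    def test_ubiquitous_surface_has_zero_idf(self):
        lex = build_document_frequencies(self.make_corpus(), {"shared"})
        assert lex.get("shared").doc_frequency == 10
        assert lex.get("shared").idf == 0.0

    def test_rare_surface_idf_is_log_n(self):
        corpus = self.make_corpus()
        corpus[0] = {"id": "0", "title": "unique", "abstract": "rareword only"}
        lex = build_document_frequencies(corpus, {"rareword"})
        assert lex.get("rareword").idf == pytest.approx(math.log(10))

    def test_counting_is_document_level(self):
        corpus = [{"id": "0", "title": "echo echo", "abstract": "echo echo echo"}]
        lex = build_document_frequencies(corpus, {"echo"})
        assert lex.get("echo").doc_frequency == 1

    def test_phrase_matches_contiguous_runs_only(self):
        corpus = [
            {"id": "0", "title": "", "abstract": "remission induction therapy"},
            {"id": "1", "title": "", "abstract": "induction of remission"},
        ]
        lex = build_document_frequencies(corpus, {"remission induction"})
        assert lex.get("remission induction").doc_frequency == 1

    def test_zero_frequency_surfaces_are_omitted(self):
        lex = build_document_frequencies(self.make_corpus(), {"absent", "shared"})
        assert lex.get("absent") is None

    @settings(deadline=None, max_examples=50)
    @given(st.data())
    def test_phrase_matching_agrees_with_token_scan(self, data):
        vocab = ["a", "b", "c", "d"]
        docs = data.draw(
            st.lists(st.lists(st.sampled_from(vocab), min_size=1, max_size=8),
                     min_size=1, max_size=6)
        )
        phrase = data.draw(st.lists(st.sampled_from(vocab), min_size=2, max_size=3))
        surface = " ".join(phrase)
        corpus = [{"id": str(i), "title": "", "abstract": " ".join(d)} for i, d in enumerate(docs)]
        expected = sum(
            1 for d in docs
            if any(d[i : i + len(phrase)] == phrase for i in range(len(d) - len(phrase) + 1))
        )
        lex = build_document_frequencies(corpus, {surface})
        got = lex.get(surface).doc_frequency if lex.get(surface) else 0
        assert got == expected

    def test_idf_decreases_with_doc_frequency(self):
        n = 50
        idfs = [math.log(n / df) for df in range(1, n + 1)]
        assert all(a > b for a, b in zip(idfs, idfs[1:]))


class TestEmbeddings:
    def test_load_parses_dimension_and_vectors(self, tmp_path):
        p = tmp_path / "emb.txt"
        p.write_text("alpha 0.1 0.2 0.3 0.4\nbeta 1 0 0 0\ngamma 0 1 0 0\n")
        store = load_embeddings(str(p))
        assert store.dimension == 4
        assert len(store) == 3
        np.testing.assert_allclose(store.get("beta"), [1, 0, 0, 0])

    def test_underscore_surfaces_become_phrases(self, tmp_path):
        p = tmp_path / "emb.txt"
        p.write_text("t_cell 0.1 0.2\n")
        store = load_embeddings(str(p))
        assert "t cell" in store
        assert store.get("t cell") is not None

    def test_inconsistent_dimension_reports_line(self, tmp_path):
        p = tmp_path / "emb.txt"
        p.write_text("a 1 2 3\nb 1 2\n")
        with pytest.raises(ValueError, match="line 2"):
            load_embeddings(str(p))

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "emb.txt"
        p.write_text("")
        with pytest.raises(ValueError):
            load_embeddings(str(p))

    def test_absent_surface_distinguishable_from_zero(self, tmp_path):
        p = tmp_path / "emb.txt"
        p.write_text("zero 0 0\n")
        store = load_embeddings(str(p))
        assert store.get("zero") is not None
        assert store.get("missing") is None

    def test_roundtrip_save_load(self, tmp_path):
        p = tmp_path / "emb.txt"
        p.write_text("t_cell 0.5 -0.25\nword 1 2\n")
        store = load_embeddings(str(p))
        q = tmp_path / "emb2.txt"
        store.save(str(q))
        again = load_embeddings(str(q))
        np.testing.assert_allclose(again.get("t cell"), store.get("t cell"))


class TestCosine:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1.0),
            ([1.0, 0.0], [0.0, 1.0], 0.0),
            ([1.0, 1.0], [1.0, 0.0], 0.7071),
            ([1.0, 0.0], [-1.0, 0.0], -1.0),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert cosine_similarity(a, b) == pytest.approx(expected, abs=1e-4)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=5), rng.normal(size=5)
        assert cosine_similarity(a, b) == pytest.approx(cosine_similarity(b, a))

    def test_zero_vector_scores_zero_not_error(self):
        assert cosine_similarity([0.0, 0.0], [1.0, 2.0]) == 0.0

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            cosine_similarity([1.0], [1.0, 2.0])


def test_tokenizer_keeps_hyphenated_biomedical_tokens():
    assert "mir-21" in tokenize_simple("Is miR-21 related to carcinogenesis?")
    toks = tokenize_simple("drug/medication interactions")
    assert "drug" in toks and "medication" in toks


def test_vocab_entry_invariants():
    with pytest.raises(ValueError):
        VocabEntry("x", 0, 1.0)
    with pytest.raises(ValueError):
        VocabEntry("a b c d e", 1, 1.0)


def test_lexicon_tsv_roundtrip(tmp_path):
    lex = build_document_frequencies(
        [{"id": "0", "title": "alpha beta", "abstract": "gamma"}], {"alpha", "gamma"}
    )
    p = tmp_path / "lex.tsv"
    lex.save_tsv(str(p))
    again = Lexicon.load_tsv(str(p))
    assert again.n_docs == lex.n_docs
    assert again.get("alpha").idf == lex.get("alpha").idf
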