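"""Exact answer phrase extraction for factoid questions.

From the top-10 ranked answer sentences, candidates come from one of two
paths.  When the question's focus maps to a recognized entity type, the
*entity path* returns the unique entities of that type in first-occurrence
order, unscored.  Otherwise the *NP path* harvests every noun phrase
(leading determiners, demonstratives, predeterminers, comparatives,
superlatives, cardinals and adverbs stripped; 3-5-token NPs contribute
their subphrases too), filters out bare generic type words and anything
embedding-similar (cosine ≥ 0.8) to a question noun/NP, and ranks the rest
by cos(candidate, focus) × TF × IDF with term frequencies counted over the
ten candidate sentences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotation import Annotator, annotate
from .gazetteer import ENTITY_TYPES, Gazetteer, tag_entities
from .lexicon import EmbeddingStore, Lexicon, cosine_similarity, tokenize_simple
from .question import AnalyzedQuestion
from .ranking import AnswerCandidate

__all__ = [
    "ExactAnswerCandidate",
    "DEFAULT_GENERIC_TERMS",
    "harvest_candidates",
    "filter_candidates",
    "score_and_rank",
    "extract_exact_answers",
]

MAX_SENTENCES = 10

#: non-informative bare type words removed from candidate sets
DEFAULT_GENERIC_TERMS = frozenset(ENTITY_TYPES) | {"protein", "gene", "drug", "disease"}

_STRIP_POS = {"DT", "PDT", "WDT", "PRP", "JJR", "JJS", "RBR", "RBS", "CD", "RB"}


@dataclass(frozen=True)
class ExactAnswerCandidate:
    phrase: str
    sentence_rank: int  # 1-based rank of the source sentence
    path: str  # entity | np
    score: float = 0.0

    def to_dict(self) -> dict:
        return {
            "phrase": self.phrase,
            "score": self.score,
            "path": self.path,
            "sentence_rank": self.sentence_rank,
        }


def _strip_np_lead(tokens) -> list:
    toks = list(tokens)
    while toks and toks[0].pos in _STRIP_POS:
        toks = toks[1:]
    return toks


def harvest_candidates(
    top_sentences: Sequence[AnswerCandidate],
    focus_entity_type: str | None,
    gazetteer: Gazetteer | None = None,
    annotator: Annotator | None = None,
) -> list[ExactAnswerCandidate]:
    """Candidate phrases from the top-10 sentence pool (entity or NP path)."""
    if not top_sentences:
        raise ValueError("no candidate sentences")
    if len(top_sentences) > MAX_SENTENCES:
        raise ValueError(f"candidate pool is capped at {MAX_SENTENCES} sentences")

    out: list[ExactAnswerCandidate] = []
    seen: set[str] = set()

    if focus_entity_type is not None:
        if focus_entity_type not in ENTITY_TYPES:
            raise ValueError(f"unrecognized entity type {focus_entity_type!r}")
        for rank, cand in enumerate(top_sentences, start=1):
            mentions = cand.entities
            if not mentions and gazetteer is not None:
                mentions = tag_entities(annotate(cand.sentence, annotator), gazetteer)
            for m in mentions:
                if m.type == focus_entity_type and m.surface.lower() not in seen:
                    seen.add(m.surface.lower())
                    out.append(ExactAnswerCandidate(m.surface, rank, "entity"))
        return out

    for rank, cand in enumerate(top_sentences, start=1):
        ann = annotate(cand.sentence, annotator)
        for lo, hi in ann.noun_phrases:
            toks = _strip_np_lead(ann.tokens[lo:hi])
            if not toks:
                continue
            surface = " ".join(t.surface for t in toks)
            phrases = [surface]
            # 3-5-token NPs contribute their contiguous subphrases
            words = [t.surface for t in toks]
            if 3 <= len(words) <= 5:
                for length in range(1, len(words)):
                    for i in range(len(words) - length + 1):
                        phrases.append(" ".join(words[i : i + length]))
            for p in phrases:
                if p.lower() not in seen:
                    seen.add(p.lower())
                    out.append(ExactAnswerCandidate(p, rank, "np"))
    return out


def _question_np_surfaces(q: AnalyzedQuestion) -> list[str]:
    ann = q.annotated
    out = []
    for np in ann.noun_phrases:
        out.append(ann.np_surface(np))
    for tok in ann.tokens:
        if tok.pos.startswith("NN"):
            out.append(tok.surface)
    return out


def filter_candidates(
    cands: Sequence[ExactAnswerCandidate],
    question_nps: Iterable[str],
    embeddings: EmbeddingStore,
    generic_terms: frozenset[str] = DEFAULT_GENERIC_TERMS,
    similarity_threshold: float = 0.8,
) -> list[ExactAnswerCandidate]:
    """Remove bare generic type words and candidates too similar (cosine ≥
    threshold) to any question noun/NP — the question rarely contains its
    own answer."""
    q_surfaces = [s for s in question_nps if s and s.strip()]
    out = []
    for c in cands:
        low = c.phrase.lower()
        if low in generic_terms:
            continue
        if any(low == s.lower() for s in q_surfaces):
            continue
        too_similar = False
        for s in q_surfaces:
            sim = embeddings.similarity(c.phrase, s)
            if sim is not None and sim >= similarity_threshold:
                too_similar = True
                break
        if not too_similar:
            out.append(c)
    return out


def score_and_rank(
    cands: Sequence[ExactAnswerCandidate],
    focus_term: str | None,
    embeddings: EmbeddingStore,
    lexicon: Lexicon,
    candidate_sentences: Sequence[str],
) -> list[ExactAnswerCandidate]:
    """NP-path scoring: cos(candidate, focus) × TF × IDF, descending.

    TF is the raw occurrence count over the candidate sentences; IDF comes
    from the corpus lexicon.  Entity-path candidates pass through unscored
    in first-occurrence order.  A candidate with no embedding (nor any
    embedded constituent token) scores 0.  Ties break by sentence rank,
    then surface.
    """
    if all(c.path == "entity" for c in cands):
        return list(cands)

    all_tokens = []
    for s in candidate_sentences:
        all_tokens.append(tokenize_simple(s))

    def tf(phrase: str) -> int:
        ptoks = tokenize_simple(phrase)
        n = len(ptoks)
        count = 0
        for toks in all_tokens:
            for i in range(len(toks) - n + 1):
                if toks[i : i + n] == ptoks:
                    count += 1
        return count

    max_idf = lexicon.max_idf()
    scored = []
    for c in cands:
        sim = embeddings.similarity(c.phrase, focus_term) if focus_term else None
        cos = sim if sim is not None else 0.0
        score = cos * tf(c.phrase) * lexicon.idf(c.phrase, default=max_idf)
        scored.append(ExactAnswerCandidate(c.phrase, c.sentence_rank, c.path, score))
    scored.sort(key=lambda c: (-c.score, c.sentence_rank, c.phrase))
    return scored


def extract_exact_answers(
    q: AnalyzedQuestion,
    top_sentences: Sequence[AnswerCandidate],
    gazetteer: Gazetteer | None,
    embeddings: EmbeddingStore,
    lexicon: Lexicon,
    annotator: Annotator | None = None,
) -> list[ExactAnswerCandidate]:
    """Full exact-answer stage: harvest, filter, score."""
    cands = harvest_candidates(
        top_sentences[:MAX_SENTENCES], q.focus_entity_type, gazetteer, annotator
    )
    if q.focus_entity_type is not None:
        return cands
    cands = filter_candidates(cands, _question_np_surfaces(q), embeddings)
    return score_and_rank(
        cands, q.focus_phrase, embeddings, lexicon,
        [c.sentence for c in top_sentences[:MAX_SENTENCES]],
    )
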