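"""Answer-sentence ranking by IDF-weighted relaxed word mover's distance.

Word mover's distance casts document similarity as optimal transport
between bag-of-embedding term distributions.  Dropping the demand-side
constraint makes the optimum closed-form: every question term ships all of
its mass to the single most similar answer term.  With IDF weights over
the *unique* question terms this gives the ranking score

    wRWMD(Q, A) = Σ_{i∈I_Q} w_i · max_{j∈I_A} cossim(v_i, v_j) / Σ_k w_k

a similarity in [-1, 1] (1 − wRWMD is the corresponding distance; either
convention yields the same order).  Sentences from the retrieved abstracts
(title counted as sentence 0) are scored against the question and sorted
descending; factoid questions are additionally filtered so an answer must
contain an entity of the question's focus type, and definition questions
promote sentences matching lexical definition patterns.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .annotation import AnnotatedText, Annotator, annotate
from .gazetteer import EntityMention, Gazetteer, tag_entities
from .lexicon import EmbeddingStore, Lexicon, cosine_similarity, tokenize_simple
from .question import AnalyzedQuestion
from .retrieval import DocumentRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AnswerCandidate",
    "segment_sentences",
    "extract_terms",
    "wrwmd_similarity",
    "rank_candidates",
    "tag_candidates",
    "filter_by_focus_type",
    "match_definition_patterns",
]


@dataclass
class AnswerCandidate:
    sentence: str
    doc_id: str
    sentence_index: int
    wrwmd_score: float
    rerank_prob: float | None = None
    entities: list[EntityMention] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sentence": self.sentence,
            "doc_id": self.doc_id,
            "sentence_index": self.sentence_index,
            "score": self.wrwmd_score,
            "rerank_prob": self.rerank_prob,
            "entities": [
                {"surface": m.surface, "type": m.type} for m in self.entities
            ],
        }


def segment_sentences(doc: DocumentRecord, annotator: Annotator | None = None) -> list[str]:
    """Title (sentence 0) followed by the abstract's sentences."""
    sentences: list[str] = []
    if doc.title.strip():
        sentences.append(doc.title.strip())
    if doc.abstract.strip():
        ann = annotate(doc.abstract, annotator)
        for si in range(len(ann.sentences)):
            s = ann.sentence_text(si).strip()
            if s:
                sentences.append(s)
    return sentences


def extract_terms(
    text: str,
    lexicon: Lexicon | None = None,
    stopwords: frozenset[str] = frozenset(),
) -> list[str]:
    """Unique scoring terms of a text, in first-occurrence order.

    Vocabulary phrases (2-4 tokens) replace their constituent words via
    greedy longest-match left-to-right; stop-words are removed.
    """
    toks = tokenize_simple(text)
    phrases = lexicon.phrases() if lexicon is not None else set()
    max_len = max((len(p.split()) for p in phrases), default=1)
    out: list[str] = []
    seen: set[str] = set()
    i = 0
    while i < len(toks):
        matched = False
        for n in range(min(max_len, len(toks) - i), 1, -1):
            cand = " ".join(toks[i : i + n])
            if cand in phrases:
                if cand not in seen:
                    seen.add(cand)
                    out.append(cand)
                i += n
                matched = True
                break
        if not matched:
            t = toks[i]
            if t not in stopwords and t not in seen:
                seen.add(t)
                out.append(t)
            i += 1
    return out


def wrwmd_similarity(
    question_terms: dict[str, float],
    answer_terms: set[str] | list[str],
    embeddings: EmbeddingStore,
) -> float:
    """Weighted relaxed WMD similarity between unique term sets.

    Each question term contributes its maximum cosine similarity to any
    answer term, weighted by IDF and normalized by the weight sum.  A
    question term with no embedding contributes 1 when its exact surface
    occurs in the answer and 0 otherwise (rare biomedical tokens keep their
    signal).  An empty answer scores 0.
    """
    q = {s.lower(): w for s, w in question_terms.items() if w > 0}
    if not q:
        raise ValueError("question has no positively weighted terms")
    a = {s.lower() for s in answer_terms}
    if not a:
        return 0.0
    a_vecs = [(s, embeddings.get(s)) for s in sorted(a)]
    a_embedded = [(s, v) for s, v in a_vecs if v is not None]

    num = 0.0
    den = 0.0
    for surface, w in q.items():
        den += w
        qv = embeddings.get(surface)
        if qv is None:
            best = 1.0 if surface in a else 0.0
        else:
            best = None
            for s, av in a_embedded:
                c = cosine_similarity(qv, av)
                if best is None or c > best:
                    best = c
            if surface in a:
                best = 1.0 if best is None else max(best, 1.0)
            if best is None:
                best = 0.0
        num += w * best
    return num / den


def question_term_weights(
    q: AnalyzedQuestion,
    lexicon: Lexicon,
    stopwords: frozenset[str] = frozenset(),
) -> dict[str, float]:
    """IDF weights for the question's unique scoring terms (OOV terms get
    the maximum observed IDF)."""
    terms = extract_terms(q.annotated.text, lexicon, stopwords)
    max_idf = lexicon.max_idf()
    return {t: lexicon.idf(t, default=max_idf) for t in terms}


def rank_candidates(
    q: AnalyzedQuestion,
    docs: list[DocumentRecord],
    lexicon: Lexicon,
    embeddings: EmbeddingStore,
    annotator: Annotator | None = None,
    stopwords: frozenset[str] = frozenset(),
) -> list[AnswerCandidate]:
    """Score every sentence of every document and sort by similarity.

    The sort is stable: equal scores preserve document order, then
    sentence order.
    """
    if not docs:
        raise ValueError("no documents to rank")
    qw = question_term_weights(q, lexicon, stopwords)
    cands: list[AnswerCandidate] = []
    for doc in docs:
        for si, sent in enumerate(segment_sentences(doc, annotator)):
            terms = extract_terms(sent, lexicon, stopwords)
            score = wrwmd_similarity(qw, terms, embeddings) if terms else 0.0
            cands.append(AnswerCandidate(sent, doc.id, si, score))
    cands.sort(key=lambda c: -c.wrwmd_score)  # stable: ties keep doc order
    return cands


def tag_candidates(
    cands: list[AnswerCandidate],
    gazetteer: Gazetteer,
    annotator: Annotator | None = None,
) -> None:
    """Attach gazetteer entity mentions to each candidate, in place."""
    for c in cands:
        ann = annotate(c.sentence, annotator)
        c.entities = tag_entities(ann, gazetteer)


def filter_by_focus_type(
    cands: list[AnswerCandidate], focus_entity_type: str
) -> list[AnswerCandidate]:
    """Keep only candidates carrying at least one entity of the focus type
    (order preserved).  May return an empty list; callers fall back to the
    unfiltered ranking in that case."""
    return [
        c for c in cands if any(m.type == focus_entity_type for m in c.entities)
    ]


def _definition_patterns(focus: str) -> list[re.Pattern]:
    f = re.escape(focus)
    return [
        re.compile(rf"\b{f}\b\s+(is|are)\s+(a|an|the)\b", re.IGNORECASE),
        re.compile(rf"\b{f}\b\s*,\s*(a|an)\b", re.IGNORECASE),
        re.compile(rf"\b{f}\b\s+(is|are)\s+defined\s+as\b", re.IGNORECASE),
        re.compile(rf"\b{f}\b\s+(refers?|referring)\s+to\b", re.IGNORECASE),
    ]


def match_definition_patterns(
    focus_phrase: str, cands: list[AnswerCandidate]
) -> list[AnswerCandidate]:
    """Promote candidates matching a definition pattern for the focus
    ("X is a ...", "X, a ...", "X is defined as ...", "X refers to ...")
    above all non-matching ones; both groups keep their similarity order."""
    pats = _definition_patterns(focus_phrase)
    hits = [c for c in cands if any(p.search(c.sentence) for p in pats)]
    misses = [c for c in cands if not any(p.search(c.sentence) for p in pats)]
    return hits + misses
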