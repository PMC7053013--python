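"""End-to-end orchestration: question in → ranked answers (+ exact answers).

Composition per question: analyze → candidate terms → boolean query →
(optional force-include of classifier-selected keywords) → iterative
retrieval → sentence segmentation → wRWMD ranking → focus-type /
definition-pattern filtering → (optional supervised reranking) → exact
answer extraction for factoid questions.  Every relaxation drop and stage
decision is logged at debug level so the retrieval behavior is auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

from .annotation import Annotator, load_nominalizations, load_stopwords
from .evaluation import EvalReport, GoldQuestion, JudgedRanking, align_gold, evaluate
from .exact import extract_exact_answers
from .gazetteer import Gazetteer, load_gazetteer, tag_entities
from .lexicon import EmbeddingStore, Lexicon, build_document_frequencies, load_embeddings
from .question import AnalyzedQuestion, analyze_question, generate_candidate_terms
from .ranking import (
    AnswerCandidate,
    filter_by_focus_type,
    match_definition_patterns,
    rank_candidates,
    tag_candidates,
)
from .reranker import PairScorer, rerank
from .retrieval import (
    InMemoryIndex,
    build_query,
    iterative_retrieve,
    read_corpus_jsonl,
)
from .selector import KeywordSelector, force_include, select_keywords

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "QAPipeline", "Answer"]


@dataclass
class PipelineConfig:
    index_path: str | None = None
    corpus_path: str | None = None
    embeddings_path: str = ""
    gazetteer_paths: tuple[str, ...] = ()
    selector_model_path: str | None = None
    reranker_model_path: str | None = None
    top_k: int = 10
    max_hits: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class Answer:
    question: str
    exhausted: bool
    iterations: int
    candidates: list[AnswerCandidate]
    exact_answers: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "question": self.question,
                "exhausted": self.exhausted,
                "iterations": self.iterations,
                "answers": [
                    dict(rank=i + 1, **c.to_dict())
                    for i, c in enumerate(self.candidates)
                ],
                "exact_answers": [e.to_dict() for e in self.exact_answers],
            },
            indent=1,
            sort_keys=True,
        )


class QAPipeline:
    """Holds the loaded resources and answers questions end to end."""

    def __init__(
        self,
        index: InMemoryIndex,
        lexicon: Lexicon,
        embeddings: EmbeddingStore,
        gazetteer: Gazetteer | None = None,
        annotator: Annotator | None = None,
        selector: KeywordSelector | None = None,
        reranker: PairScorer | None = None,
        top_k: int = 10,
        max_hits: int = 1000,
    ):
        self.index = index
        self.lexicon = lexicon
        self.embeddings = embeddings
        self.gazetteer = gazetteer
        self.annotator = annotator
        self.selector = selector
        self.reranker = reranker
        self.top_k = top_k
        self.max_hits = max_hits
        self.nominalizations = load_nominalizations()
        self.stopwords = load_stopwords()

    @classmethod
    def from_config(cls, config: PipelineConfig, **kwargs) -> "QAPipeline":
        if config.index_path:
            index = InMemoryIndex.load(config.index_path)
        elif config.corpus_path:
            index = InMemoryIndex(read_corpus_jsonl(config.corpus_path))
        else:
            raise ValueError("config needs an index_path or corpus_path")
        lexicon = build_document_frequencies(
            [{"title": d.title, "abstract": d.abstract} for d in index.docs.values()],
            vocabulary={
                t
                for d in index.docs.values()
                for t in (d.title + " " + d.abstract).lower().split()
            },
        )
        embeddings = load_embeddings(config.embeddings_path)
        gazetteer = (
            load_gazetteer(config.gazetteer_paths) if config.gazetteer_paths else None
        )
        return cls(
            index, lexicon, embeddings, gazetteer,
            top_k=config.top_k, max_hits=config.max_hits, **kwargs,
        )

    def analyze(self, question: str) -> AnalyzedQuestion:
        return analyze_question(
            question, self.annotator, gazetteer=self.gazetteer
        )

    def answer(self, question: str, use_reranker: bool = True,
               with_exact: bool = True, top_k: int | None = None) -> Answer:
        top_k = self.top_k if top_k is None else top_k
        try:
            q = self.analyze(question)
            logger.debug("question type=%s focus=%r entity_type=%r",
                         q.question_type, q.focus_phrase, q.focus_entity_type)
            candidates = generate_candidate_terms(
                q, self.lexicon, self.nominalizations, stopwords=self.stopwords
            )
            q_entities = (
                tag_entities(q.annotated, self.gazetteer) if self.gazetteer else []
            )
            query = build_query(candidates, q_entities, self.lexicon)
            if self.selector is not None:
                keywords = select_keywords(q.annotated, self.selector, self.embeddings)
                logger.debug("selector keywords: %s", keywords)
                query = force_include(query, keywords)
            result, final_query = iterative_retrieve(
                query, self.index, self.lexicon, max_hits=self.max_hits
            )
            for surface, origin in final_query.history:
                logger.debug("dropped %r from construct %d", surface, origin)
            if not result.ids:
                return Answer(question, True, final_query.iteration, [])

            docs = [self.index.docs[i] for i in result.ids]
            cands = rank_candidates(
                q, docs, self.lexicon, self.embeddings, self.annotator, self.stopwords
            )
            if self.gazetteer is not None:
                tag_candidates(cands, self.gazetteer, self.annotator)
                if q.focus_entity_type is not None:
                    kept = filter_by_focus_type(cands, q.focus_entity_type)
                    if kept:
                        cands = kept
                    else:
                        logger.warning(
                            "focus-type filter removed everything; "
                            "falling back to unfiltered ranking"
                        )
            if q.question_type == "definition" and q.focus_phrase:
                cands = match_definition_patterns(q.focus_phrase, cands)
            if use_reranker and self.reranker is not None:
                cands = rerank(cands, self.reranker, question)

            top = cands[:top_k]
            exact = []
            if with_exact and q.question_type == "focus":
                exact = extract_exact_answers(
                    q, top[:10], self.gazetteer, self.embeddings, self.lexicon,
                    self.annotator,
                )
            return Answer(question, False, final_query.iteration, top, exact)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed on {question!r}: {exc}") from exc

    def run_eval(
        self, gold: Sequence[GoldQuestion], use_reranker: bool = True,
        window: int = 200,
    ) -> tuple[EvalReport, list[JudgedRanking]]:
        """Answer each gold question and judge heuristically by gold-string
        alignment (human judging remains authoritative)."""
        judged = []
        for gq in gold:
            ans = self.answer(
                gq.body, use_reranker=use_reranker, with_exact=False, top_k=window
            )
            judged.append(
                align_gold(
                    gq.id,
                    [c.sentence for c in ans.candidates],
                    gq.answer_strings(),
                    window=window,
                )
            )
        return evaluate(judged, heuristic=True), judged
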