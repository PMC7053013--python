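"""Supervised answer-candidate reranking as sentence-pair classification.

Training data comes from judged baseline runs: for each question whose
first correct answer appears within the candidate pool (100 by default),
that sentence is the one positive and the remaining pool members are
negatives — a deliberately noisy labeling, since correct answers below the
first annotated occurrence stay negative.  A pluggable binary classifier
maps (question, sentence) pairs to answer probabilities, which reorder the
similarity-ranked candidates.

The default backend is a seeded bag-of-embeddings logistic regression:
deterministic, CPU-only, dependency-light.  A transformer fine-tuning
adapter can be plugged in through the same two-method contract; rerank
quality is backend-agnostic by design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .lexicon import EmbeddingStore, tokenize_simple
from .ranking import AnswerCandidate

__all__ = [
    "SentencePairExample",
    "RerankerConfig",
    "JudgedRun",
    "build_training_pairs",
    "PairScorer",
    "SentencePairReranker",
    "fine_tune",
    "rerank",
]


@dataclass(frozen=True)
class SentencePairExample:
    question: str
    sentence: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass(frozen=True)
class RerankerConfig:
    max_sequence_length: int = 64
    batch_size: int = 16
    epochs: int = 3
    candidate_pool: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_sequence_length", "batch_size", "epochs", "candidate_pool"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class JudgedRun:
    """A question's ranked candidate sentences plus the 1-based rank of the
    first annotated correct answer (None when no candidate is correct)."""

    question: str
    candidates: tuple[str, ...]
    first_correct_rank: int | None


def build_training_pairs(
    judged_runs: Sequence[JudgedRun], config: RerankerConfig = RerankerConfig()
) -> list[SentencePairExample]:
    """One positive and pool-1 negatives per answerable question.

    Questions whose first correct answer lies outside the pool (or is
    absent) contribute nothing.
    """
    pairs: list[SentencePairExample] = []
    for run in judged_runs:
        pool = run.candidates[: config.candidate_pool]
        rank = run.first_correct_rank
        if rank is None or rank > len(pool):
            continue
        for i, sent in enumerate(pool, start=1):
            pairs.append(SentencePairExample(run.question, sent, int(i == rank)))
    return pairs


class PairScorer(Protocol):
    def score(self, question: str, sentence: str) -> float:  # pragma: no cover
        ...


class SentencePairReranker(BaseEstimator):
    """Bag-of-embeddings sentence-pair classifier (scikit-learn style).

    Pair features are the mean embedding of each side plus their absolute
    difference and elementwise product; the classifier head is a seeded
    logistic regression.  ``score`` returns the answer probability for a
    (question, sentence) pair.
    """

    def __init__(self, embeddings: EmbeddingStore | None = None,
                 max_sequence_length: int = 64, seed: int = 0, C: float = 1.0):
        self.embeddings = embeddings
        self.max_sequence_length = max_sequence_length
        self.seed = seed
        self.C = C

    def _embed(self, text: str) -> np.ndarray:
        toks = tokenize_simple(text)[: self.max_sequence_length]
        vecs = [self.embeddings.get(t) for t in toks]
        vecs = [v for v in vecs if v is not None]
        if not vecs:
            return np.zeros(self.embeddings.dimension)
        return np.mean(vecs, axis=0)

    def _features(self, question: str, sentence: str) -> np.ndarray:
        q = self._embed(question)
        s = self._embed(sentence)
        return np.concatenate([q, s, np.abs(q - s), q * s])

    def fit(self, pairs: Sequence[SentencePairExample], y=None):
        if self.embeddings is None:
            raise ValueError("an EmbeddingStore is required")
        labels = np.array([p.label for p in pairs])
        if labels.sum() == 0 or labels.sum() == len(labels):
            raise ValueError("training pairs are single-class")
        X = np.stack([self._features(p.question, p.sentence) for p in pairs])
        # training runs are one positive vs pool-1 negatives; balanced class
        # weights keep the probability scale usable at the 0.5 threshold
        self.clf_ = LogisticRegression(
            max_iter=1000, C=self.C, random_state=self.seed,
            class_weight="balanced",
        ).fit(X, labels)
        return self

    def score(self, question: str, sentence: str) -> float:
        x = self._features(question, sentence)[None]
        return float(self.clf_.predict_proba(x)[0, 1])


def fine_tune(
    pairs: Sequence[SentencePairExample],
    config: RerankerConfig = RerankerConfig(),
    backend: BaseEstimator | None = None,
    embeddings: EmbeddingStore | None = None,
) -> PairScorer:
    """Train the pair classifier and return a scorer handle.

    ``backend`` may be any estimator with ``fit(pairs)`` and
    ``score(question, sentence)``; the default is the bag-of-embeddings
    logistic regression.  Degenerate single-class data raises.
    """
    if not pairs:
        raise ValueError("no training pairs")
    model = backend
    if model is None:
        model = SentencePairReranker(
            embeddings=embeddings,
            max_sequence_length=config.max_sequence_length,
            seed=config.seed,
        )
    model.fit(pairs)
    return model


def rerank(
    cands: Sequence[AnswerCandidate],
    scorer: PairScorer | Callable[[str, str], float],
    question: str,
) -> list[AnswerCandidate]:
    """Reorder candidates by descending answer probability.

    The incoming (wRWMD) order is the stable tie-break, and the output is a
    permutation of the input.  Probabilities are recorded on the candidates.
    """
    fn = scorer.score if hasattr(scorer, "score") else scorer
    out = list(cands)
    for c in out:
        c.rerank_prob = float(fn(question, c.sentence))
    out.sort(key=lambda c: -c.rerank_prob)  # stable
    return out
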