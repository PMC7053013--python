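"""Evaluation: mean reciprocal rank, Precision@1, and gold-answer alignment.

A *judged ranking* records, per question, the 1-based rank of the first
correct answer candidate (or none when no candidate within the judging
window was correct).  MRR = (1/N) Σ 1/rank(Q_i) with unanswered questions
contributing 0; Precision@1 is the fraction of questions whose first
returned candidate is correct.  P@1 ≤ MRR always.

`align_gold` offers a heuristic stand-in for human judging: the first
candidate (within a window) containing any gold answer string at token
boundaries supplies the rank.  Reports carry a flag distinguishing
heuristic from human judgments.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "JudgedRanking",
    "EvalReport",
    "mrr",
    "precision_at_1",
    "align_gold",
    "evaluate",
    "read_bioasq_json",
    "GoldQuestion",
]


@dataclass(frozen=True)
class JudgedRanking:
    question_id: str
    rank: int | None  # 1-based rank of the first correct answer

    def __post_init__(self) -> None:
        if self.rank is not None and self.rank < 1:
            raise ValueError("rank must be >= 1 when present")


@dataclass(frozen=True)
class EvalReport:
    n_questions: int
    mrr: float
    precision_at_1: float
    heuristic: bool = False

    def to_dict(self) -> dict:
        return {
            "n_questions": self.n_questions,
            "mrr": self.mrr,
            "precision_at_1": self.precision_at_1,
            "heuristic_judgments": self.heuristic,
        }


def mrr(judged: Sequence[JudgedRanking]) -> float:
    """Mean reciprocal rank; unanswered questions contribute 0."""
    if not judged:
        raise ValueError("no judged rankings")
    return sum(1.0 / j.rank for j in judged if j.rank is not None) / len(judged)


def precision_at_1(judged: Sequence[JudgedRanking]) -> float:
    """Fraction of questions answered by the first returned candidate."""
    if not judged:
        raise ValueError("no judged rankings")
    return sum(1 for j in judged if j.rank == 1) / len(judged)


def evaluate(judged: Sequence[JudgedRanking], heuristic: bool = False) -> EvalReport:
    return EvalReport(len(judged), mrr(judged), precision_at_1(judged), heuristic)


def _contains_at_token_boundary(haystack: str, needle: str) -> bool:
    pat = r"(?<![A-Za-z0-9])" + re.escape(needle.strip().lower()) + r"(?![A-Za-z0-9])"
    return re.search(pat, haystack.lower()) is not None


def align_gold(
    question_id: str,
    ranked_sentences: Sequence[str],
    gold_answers: Iterable[str],
    window: int = 200,
) -> JudgedRanking:
    """Heuristic judgment: rank of the first candidate sentence within
    ``window`` containing any gold answer string (case-insensitive, token
    boundaries).  For list questions, any one list item suffices.
    """
    gold = [g for g in gold_answers if g and g.strip()]
    if not gold:
        raise ValueError("gold answers are empty")
    for i, sent in enumerate(ranked_sentences[:window], start=1):
        if any(_contains_at_token_boundary(sent, g) for g in gold):
            return JudgedRanking(question_id, i)
    return JudgedRanking(question_id, None)


@dataclass(frozen=True)
class GoldQuestion:
    id: str
    body: str
    type: str
    exact_answers: tuple[str, ...]
    ideal_answers: tuple[str, ...]

    def answer_strings(self) -> list[str]:
        return [*self.exact_answers, *self.ideal_answers]


def _flatten_answers(raw) -> tuple[str, ...]:
    if raw is None:
        return ()
    if isinstance(raw, str):
        return (raw,)
    out: list[str] = []
    for item in raw:
        if isinstance(item, str):
            out.append(item)
        else:
            out.extend(str(x) for x in item)
    return tuple(out)


def read_bioasq_json(path: str) -> list[GoldQuestion]:
    """Read a BioASQ-style gold file: {"questions": [{"body", "type",
    "exact_answer", "ideal_answer", ...}]}.  Exact answers may be strings,
    lists, or lists of synonym lists; all are flattened."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    out = []
    for i, q in enumerate(payload.get("questions", [])):
        out.append(
            GoldQuestion(
                id=str(q.get("id", i)),
                body=q["body"],
                type=q.get("type", "factoid"),
                exact_answers=_flatten_answers(q.get("exact_answer")),
                ideal_answers=_flatten_answers(q.get("ideal_answer")),
            )
        )
    return out
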