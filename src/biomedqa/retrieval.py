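"""Boolean keyword retrieval with greedy iterative query relaxation.

The query model is a conjunction of *search constructs*: each construct is
an OR-group of surface variants of one question term (an NP with its number
variants and acronyms, or a verb with its conjugations and nominalizations)
and carries a weight

    w_cons = (1/|ST|) [ Σ_{i∈V} w_i  +  Σ_{i∉V} min_j w_ij ]

where |ST| is the number of disjuncts, in-vocabulary disjuncts contribute
their IDF weight w_i, and out-of-vocabulary disjuncts contribute the
minimum IDF over their constituent tokens.

A query usually starts too specific to match anything, so disjuncts are
dropped greedily — verbs first, then the OR-group with the least maximum
weight, lowest-weight disjunct each step, entity-focus groups protected
until everything else is a singleton — until the index returns documents.

The search backend is an interface; the reference implementation is an
in-memory inverted index with token positions (phrases must match as
contiguous token runs).  An adapter to an external search engine can
implement the same two methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

from .gazetteer import EntityMention
from .lexicon import Lexicon, tokenize_simple
from .question import CandidateTerm

__all__ = [
    "DocumentRecord",
    "SearchConstruct",
    "KeywordQuery",
    "RetrievalResult",
    "SearchBackend",
    "InMemoryIndex",
    "construct_weight",
    "build_query",
    "evaluate_boolean",
    "iterative_retrieve",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
]


@dataclass(frozen=True)
class DocumentRecord:
    id: str
    title: str
    abstract: str


def read_corpus_jsonl(path: str) -> list[DocumentRecord]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            docs.append(DocumentRecord(str(rec["id"]), rec.get("title", ""), rec.get("abstract", "")))
    return docs


def write_corpus_jsonl(docs: Iterable[DocumentRecord], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(json.dumps({"id": d.id, "title": d.title, "abstract": d.abstract}) + "\n")


@dataclass
class SearchConstruct:
    """A weighted OR-group of search terms; conjoined into a KeywordQuery.

    ``disjuncts`` is kept sorted descending by weight (ties lexicographic);
    ``origin`` preserves the construct's left-to-right question order for
    deterministic tie-breaks during relaxation.
    """

    disjuncts: list[tuple[str, float]]
    kind: str  # verb | np | entity | word | subphrase
    protected: bool = False
    weight: float = 0.0
    origin: int = 0

    def sort_disjuncts(self) -> None:
        self.disjuncts.sort(key=lambda d: (-d[1], d[0]))

    @property
    def max_disjunct_weight(self) -> float:
        return self.disjuncts[0][1] if self.disjuncts else 0.0

    def surfaces(self) -> list[str]:
        return [s for s, _ in self.disjuncts]


@dataclass
class KeywordQuery:
    constructs: list[SearchConstruct]
    iteration: int = 0
    history: list[tuple[str, int]] = field(default_factory=list)

    def active(self) -> bool:
        return any(c.disjuncts for c in self.constructs)


@dataclass
class RetrievalResult:
    ids: list[str]
    total_hits: int
    exhausted: bool = False


class SearchBackend(Protocol):
    """Backend contract: boolean conjunction-of-disjunction evaluation."""

    def matching_docs(self, constructs: Sequence[SearchConstruct]) -> list[str]:
        """Doc ids matching every construct, ordered by backend score."""
        ...


def construct_weight(st: SearchConstruct, lexicon: Lexicon) -> float:
    """The OR-group weight w_cons (average over disjuncts; see module doc).

    OOV disjuncts fall back to the minimum IDF over their tokens, tokens
    themselves absent from the vocabulary counting 0.
    """
    if not st.disjuncts:
        raise ValueError("empty search construct")
    total = 0.0
    for surface, _ in st.disjuncts:
        if surface in lexicon:
            total += lexicon.idf(surface)
        else:
            toks = surface.split()
            total += min(lexicon.idf(t, default=0.0) for t in toks)
    return total / len(st.disjuncts)


def build_query(
    candidates: Sequence[CandidateTerm],
    question_entities: Sequence[EntityMention],
    lexicon: Lexicon,
) -> KeywordQuery:
    """Assemble the conjunction of OR-groups from weighted candidate terms.

    One construct per NP (the NP plus its number variants and acronym
    expansions), one per verb (plus conjugations and nominalizations), one
    per subphrase and per individual NP word.  A construct whose surface
    matches a recognized question entity is flagged protected (it likely
    carries the question's focus and is dropped only as a last resort).
    """
    if not candidates:
        raise ValueError("no candidate terms")
    entity_surfaces = {m.surface.lower() for m in question_entities}

    parents: dict[str, SearchConstruct] = {}
    order: list[SearchConstruct] = []
    for term in candidates:
        if term.kind in {"verb", "np"}:
            st = SearchConstruct([(term.surface, term.weight)], term.kind, origin=len(order))
            parents[term.surface] = st
            order.append(st)
        elif term.kind in {"np_word", "subphrase", "entity"}:
            kind = "word" if term.kind == "np_word" else term.kind
            st = SearchConstruct([(term.surface, term.weight)], kind, origin=len(order))
            order.append(st)
    for term in candidates:
        if term.kind == "expansion" and term.variant_of in parents:
            parents[term.variant_of].disjuncts.append((term.surface, term.weight))

    for st in order:
        st.sort_disjuncts()
        if any(s in entity_surfaces for s in st.surfaces()):
            st.protected = True
            if st.kind not in {"verb"}:
                st.kind = "entity"
        st.weight = construct_weight(st, lexicon)
    return KeywordQuery(order)


class InMemoryIndex:
    """Reference backend: inverted index with token positions.

    A document matches a query iff every construct has at least one
    disjunct present in title+abstract, phrases as contiguous token runs.
    Matching documents are scored by the summed weight of the best matched
    disjunct per construct (ties broken by doc id) — a deterministic
    stand-in for a production engine's relevance score.
    """

    def __init__(self, docs: Iterable[DocumentRecord]):
        self.docs: dict[str, DocumentRecord] = {}
        self._postings: dict[str, dict[str, list[int]]] = {}
        for doc in docs:
            if doc.id in self.docs:
                raise ValueError(f"duplicate doc id {doc.id!r}")
            self.docs[doc.id] = doc
            toks = tokenize_simple(doc.title + " " + doc.abstract)
            for pos, t in enumerate(toks):
                self._postings.setdefault(t, {}).setdefault(doc.id, []).append(pos)

    def __len__(self) -> int:
        return len(self.docs)

    def _docs_with_surface(self, surface: str) -> set[str]:
        toks = surface.lower().split()
        if not toks:
            return set()
        first = self._postings.get(toks[0])
        if first is None:
            return set()
        if len(toks) == 1:
            return set(first.keys())
        out = set()
        for doc_id, positions in first.items():
            rest = [self._postings.get(t, {}).get(doc_id) for t in toks[1:]]
            if any(r is None for r in rest):
                continue
            rest_sets = [set(r) for r in rest]
            for p in positions:
                if all(p + k + 1 in rest_sets[k] for k in range(len(rest_sets))):
                    out.add(doc_id)
                    break
        return out

    def matching_docs(self, constructs: Sequence[SearchConstruct]) -> list[str]:
        scores: dict[str, float] = {}
        alive: set[str] | None = None
        for st in constructs:
            if not st.disjuncts:
                continue
            hit_best: dict[str, float] = {}
            for surface, w in st.disjuncts:
                for doc_id in self._docs_with_surface(surface):
                    if doc_id not in hit_best or w > hit_best[doc_id]:
                        hit_best[doc_id] = w
            if alive is None:
                alive = set(hit_best)
            else:
                alive &= set(hit_best)
            for doc_id, w in hit_best.items():
                scores[doc_id] = scores.get(doc_id, 0.0) + w
            if not alive:
                return []
        if alive is None:
            return []
        return sorted(alive, key=lambda d: (-scores[d], d))

    # single-file JSON persistence
    def save(self, path: str) -> None:
        payload = {
            "docs": [
                {"id": d.id, "title": d.title, "abstract": d.abstract}
                for d in self.docs.values()
            ]
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "InMemoryIndex":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(DocumentRecord(d["id"], d["title"], d["abstract"]) for d in payload["docs"])


def evaluate_boolean(
    query: KeywordQuery, index: SearchBackend, max_hits: int | None = None
) -> RetrievalResult:
    """Evaluate the conjunction; ``total_hits`` is exact even when the
    returned id list is capped at ``max_hits``."""
    constructs = [c for c in query.constructs if c.disjuncts]
    if not constructs:
        raise ValueError("empty query")
    ids = index.matching_docs(constructs)
    total = len(ids)
    if max_hits is not None:
        ids = ids[:max_hits]
    return RetrievalResult(ids, total)


def _next_drop(query: KeywordQuery) -> SearchConstruct | None:
    """The construct to drop from next, per the relaxation policy.

    Priority: verb constructs (always first, regardless of weight), then
    unprotected multi-disjunct constructs by ascending max disjunct weight,
    then unprotected singletons, then protected constructs (multi before
    singleton) as the last resort.  Weight ties break by original
    left-to-right question order.
    """
    def keyed(cands: list[SearchConstruct]) -> SearchConstruct | None:
        if not cands:
            return None
        return min(cands, key=lambda c: (c.max_disjunct_weight, c.origin))

    cs = [c for c in query.constructs if c.disjuncts]
    for pool in (
        [c for c in cs if c.kind == "verb"],
        [c for c in cs if c.kind != "verb" and not c.protected and len(c.disjuncts) > 1],
        [c for c in cs if c.kind != "verb" and not c.protected and len(c.disjuncts) == 1],
        [c for c in cs if c.kind != "verb" and c.protected and len(c.disjuncts) > 1],
        [c for c in cs if c.kind != "verb" and c.protected and len(c.disjuncts) == 1],
    ):
        pick = keyed(pool)
        if pick is not None:
            return pick
    return None


def iterative_retrieve(
    query: KeywordQuery,
    index: SearchBackend,
    lexicon: Lexicon,
    max_hits: int = 1000,
) -> tuple[RetrievalResult, KeywordQuery]:
    """Relax the query greedily until documents are returned.

    Returns the first query state with ≥ 1 hit (ids truncated to
    ``max_hits``; the most specific non-empty state is accepted even when
    its hit count exceeds the cap).  Each step removes the lowest-weight
    disjunct of the construct chosen by :func:`_next_drop`; a construct
    emptied of disjuncts leaves the conjunction, which is what widens the
    result set.  Terminates within the total disjunct count.
    """
    if not query.active():
        raise ValueError("empty query")
    while True:
        if query.active():
            res = evaluate_boolean(query, index, max_hits=max_hits)
            if res.total_hits >= 1:
                return res, query
        else:
            return RetrievalResult([], 0, exhausted=True), query
        target = _next_drop(query)
        if target is None:
            return RetrievalResult([], 0, exhausted=True), query
        dropped_surface, _ = target.disjuncts[-1]  # lowest weight (desc sort)
        target.disjuncts.pop()
        query.history.append((dropped_surface, target.origin))
        query.iteration += 1
        if target.disjuncts:
            target.weight = construct_weight(target, lexicon)
        else:
            query.constructs = [c for c in query.constructs if c is not target]
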