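"""Phrase vocabulary, document frequencies / IDF weights, and embedding store.

The retrieval and ranking stages weight every search term by its inverse
document frequency (IDF) over the abstract corpus, and score sentences with
cosine similarities between word/phrase embedding vectors.  This module
builds that lexicon: multi-word phrases (2-4 tokens) are mined from the
corpus by a log-likelihood-ratio collocation test, document frequencies are
counted at the document level for words and phrases alike, and embeddings
are read from GloVe-style text files.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VocabEntry",
    "Lexicon",
    "EmbeddingStore",
    "PhraseCandidate",
    "mine_phrases",
    "build_document_frequencies",
    "load_embeddings",
    "cosine_similarity",
    "tokenize_simple",
]


def tokenize_simple(text: str) -> list[str]:
    """Lowercased whitespace/punctuation tokenization used for indexing.

    Keeps internal hyphens and digits together ("miR-21" stays one token),
    which matters for biomedical surface forms.
    """
    out: list[str] = []
    cur: list[str] = []
    for ch in text:
        if ch.isalnum() or (ch in "-_'" and cur):
            cur.append(ch)
        else:
            if cur:
                out.append("".join(cur).rstrip("-_'").lower())
                cur = []
    if cur:
        out.append("".join(cur).rstrip("-_'").lower())
    return [t for t in out if t]


@dataclass(frozen=True)
class VocabEntry:
    """A word or 2-4 token phrase with its document frequency and IDF weight."""

    surface: str
    doc_frequency: int
    idf: float

    def __post_init__(self) -> None:
        if self.doc_frequency < 1:
            raise ValueError("doc_frequency must be >= 1")
        ntok = len(self.surface.split())
        if not 1 <= ntok <= 4:
            raise ValueError(f"surface must be 1-4 tokens, got {ntok!r}")


@dataclass(frozen=True)
class PhraseCandidate:
    """An n-gram under consideration as a collocation phrase."""

    surface: str
    count: int
    component_counts: tuple[int, ...]
    score: float


class Lexicon:
    """Vocabulary of words/phrases with document frequencies and IDF weights."""

    def __init__(self, entries: Iterable[VocabEntry], n_docs: int):
        if n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        self.n_docs = n_docs
        self._entries: dict[str, VocabEntry] = {e.surface: e for e in entries}

    def __contains__(self, surface: str) -> bool:
        return surface.lower() in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def get(self, surface: str) -> VocabEntry | None:
        return self._entries.get(surface.lower())

    def idf(self, surface: str, default: float | None = None) -> float:
        """IDF weight of ``surface``; ``default`` (or max IDF) when absent."""
        e = self._entries.get(surface.lower())
        if e is not None:
            return e.idf
        if default is not None:
            return default
        return self.max_idf()

    def max_idf(self) -> float:
        if not self._entries:
            return 0.0
        return max(e.idf for e in self._entries.values())

    def surfaces(self) -> Iterable[str]:
        return self._entries.keys()

    def phrases(self) -> set[str]:
        """Multi-token surfaces only."""
        return {s for s in self._entries if " " in s}

    # TSV persistence: surface \t doc_frequency \t idf
    def save_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#n_docs\t{self.n_docs}\n")
            for e in sorted(self._entries.values(), key=lambda e: e.surface):
                fh.write(f"{e.surface}\t{e.doc_frequency}\t{e.idf:.10g}\n")

    @classmethod
    def load_tsv(cls, path: str) -> "Lexicon":
        entries = []
        n_docs = 1
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#n_docs\t"):
                    n_docs = int(line.split("\t")[1])
                    continue
                surface, df, idf = line.split("\t")
                entries.append(VocabEntry(surface, int(df), float(idf)))
        return cls(entries, n_docs)


def _llr_2x2(k11: float, k12: float, k21: float, k22: float) -> float:
    """Dunning log-likelihood ratio statistic for a 2x2 contingency table.

    -2 log lambda comparing the independence model against the saturated
    model; asymptotically chi-square(1) under independence.
    """

    def entropy(*ks: float) -> float:
        tot = sum(ks)
        return sum(k * math.log(k / tot) for k in ks if k > 0)

    return 2.0 * (
        entropy(k11, k12, k21, k22)
        - entropy(k11 + k12, k21 + k22)
        - entropy(k11 + k21, k12 + k22)
    )


def _ngram_llr(ngram_count: int, part_counts: Sequence[int], total: int) -> float:
    """Collocation score for an n-gram: the minimum pairwise LLR across the
    adjacent split points, which for bigrams is the classic Dunning test and
    for longer n-grams requires every adjacent join to be non-chance."""
    scores = []
    for a_count, b_count in zip(part_counts[:-1], part_counts[1:]):
        k11 = ngram_count
        k12 = max(a_count - ngram_count, 0)
        k21 = max(b_count - ngram_count, 0)
        k22 = max(total - k11 - k12 - k21, 1)
        scores.append(_llr_2x2(k11, k12, k21, k22))
    return min(scores)


def mine_phrases(
    tokenized_corpus: Sequence[Sequence[str]],
    min_count: int = 5,
    threshold: float = 30.0,
    max_n: int = 4,
) -> set[str]:
    """Mine 2..``max_n``-token phrases whose parts co-occur beyond chance.

    Adjacent-token joins are scored with Dunning's log-likelihood ratio;
    an n-gram qualifies when it occurs at least ``min_count`` times and its
    weakest adjacent join scores at least ``threshold``.  Deterministic and
    invariant to document order.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    docs = [list(d) for d in tokenized_corpus]
    if not docs or all(not d for d in docs):
        raise ValueError("corpus is empty")

    unigrams: Counter[str] = Counter()
    for d in docs:
        unigrams.update(d)
    total = sum(unigrams.values())

    accepted: set[str] = set()
    prev_level: set[tuple[str, ...]] | None = None
    for n in range(2, max_n + 1):
        grams: Counter[tuple[str, ...]] = Counter()
        for d in docs:
            for i in range(len(d) - n + 1):
                g = tuple(d[i : i + n])
                # longer n-grams only grow from accepted shorter spans: both
                # (n-1)-subspans must have passed, keeping the lattice sparse
                if prev_level is not None and (
                    g[:-1] not in prev_level or g[1:] not in prev_level
                ):
                    continue
                grams[g] += 1
        level: set[tuple[str, ...]] = set()
        for g, c in grams.items():
            if c < min_count:
                continue
            score = _ngram_llr(c, [unigrams[t] for t in g], total)
            if score >= threshold:
                level.add(g)
                accepted.add(" ".join(g))
        if not level:
            break
        prev_level = level
    return accepted


def _doc_tokens(record: Mapping[str, str]) -> list[str]:
    return tokenize_simple(
        (record.get("title") or "") + " " + (record.get("abstract") or "")
    )


def _contains_run(tokens: Sequence[str], phrase: Sequence[str]) -> bool:
    n = len(phrase)
    if n == 1:
        return phrase[0] in tokens
    for i in range(len(tokens) - n + 1):
        if tuple(tokens[i : i + n]) == tuple(phrase):
            return True
    return False


def build_document_frequencies(
    corpus: Iterable[Mapping[str, str]], vocabulary: Iterable[str]
) -> Lexicon:
    """Count, per vocabulary surface, the number of documents containing it.

    Words match as tokens; phrases as contiguous token runs over the
    title+abstract stream.  Surfaces seen in no document are omitted.
    IDF = ln(N_docs / doc_frequency).
    """
    vocab = {v.lower() for v in vocabulary}
    if not vocab:
        raise ValueError("vocabulary is empty")
    words = {v for v in vocab if " " not in v}
    phrases = [(v, v.split()) for v in vocab if " " in v]

    df: Counter[str] = Counter()
    n_docs = 0
    for rec in corpus:
        n_docs += 1
        toks = _doc_tokens(rec)
        tokset = set(toks)
        for w in words & tokset:
            df[w] += 1
        for surface, ptoks in phrases:
            if ptoks[0] in tokset and _contains_run(toks, ptoks):
                df[surface] += 1
    if n_docs == 0:
        raise ValueError("corpus is empty")
    entries = [
        VocabEntry(s, c, math.log(n_docs / c)) for s, c in df.items()
    ]
    return Lexicon(entries, n_docs)


class EmbeddingStore:
    """Word/phrase embedding vectors with cosine-similarity lookup.

    Phrases are keyed space-joined in memory; the GloVe text convention of
    underscore-joined multi-token surfaces is translated on load.  Lookup of
    an absent surface returns ``None`` (distinguishable from a zero vector).
    """

    def __init__(self, dimension: int):
        if dimension < 1:
            raise ValueError("dimension must be positive")
        self.dimension = dimension
        self._vecs: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self._vecs)

    def __contains__(self, surface: str) -> bool:
        return surface.lower() in self._vecs

    def add(self, surface: str, vector: Sequence[float]) -> None:
        v = np.asarray(vector, dtype=np.float64)
        if v.shape != (self.dimension,):
            raise ValueError(
                f"vector for {surface!r} has length {v.shape[0]}, "
                f"store dimension is {self.dimension}"
            )
        self._vecs[surface.lower()] = v

    def get(self, surface: str) -> np.ndarray | None:
        return self._vecs.get(surface.lower())

    def get_or_mean(self, surface: str) -> np.ndarray | None:
        """Vector for the surface, or the mean of its token vectors (OOV
        phrase backoff); ``None`` when no constituent token is embedded."""
        v = self.get(surface)
        if v is not None:
            return v
        parts = [self._vecs[t] for t in surface.lower().split() if t in self._vecs]
        if not parts:
            return None
        return np.mean(parts, axis=0)

    def similarity(self, a: str, b: str) -> float | None:
        va, vb = self.get_or_mean(a), self.get_or_mean(b)
        if va is None or vb is None:
            return None
        return cosine_similarity(va, vb)

    def surfaces(self) -> Iterable[str]:
        return self._vecs.keys()

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for surface, v in self._vecs.items():
                disk = surface.replace(" ", "_")
                fh.write(disk + " " + " ".join(f"{x:.6g}" for x in v) + "\n")


def load_embeddings(path: str) -> EmbeddingStore:
    """Read a GloVe-format text file: ``surface v1 ... vD`` per line.

    The dimension is inferred from the first line; any later line with a
    different number of floats raises with its line number.  Underscore-
    joined surfaces become space-joined phrases in memory.
    """
    store: EmbeddingStore | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                if line.strip() == "":
                    continue
                raise ValueError(f"line {lineno}: no vector components")
            surface = parts[0].replace("_", " ")
            try:
                vec = [float(x) for x in parts[1:] if x]
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric component") from exc
            if store is None:
                store = EmbeddingStore(len(vec))
            if len(vec) != store.dimension:
                raise ValueError(
                    f"line {lineno}: dimension {len(vec)} != {store.dimension}"
                )
            store.add(surface, vec)
    if store is None:
        raise ValueError(f"embedding file {path!r} is empty")
    return store


def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """Cosine similarity in [-1, 1]; zero vectors score 0 with a warning."""
    va = np.asarray(a, dtype=np.float64)
    vb = np.asarray(b, dtype=np.float64)
    if va.shape != vb.shape:
        raise ValueError("vectors have different lengths")
    na = float(np.linalg.norm(va))
    nb = float(np.linalg.norm(vb))
    if na == 0.0 or nb == 0.0:
        logger.warning("cosine_similarity of a zero vector; returning 0")
        return 0.0
    return float(np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0))
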