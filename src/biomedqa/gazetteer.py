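"""Lookup-based named-entity tagging for the nine biomedical entity types.

Entity recognition here is dictionary lookup, not statistical NER: each
entity type is backed by a TSV of surface forms (in production derived from
resources such as HUGO gene symbols, CDC disease names, or DrugBank drug
names; here supplied by the user or the synthetic fixture generator).
Tagging is greedy longest-match left-to-right over token n-grams, so a
3-token disease name wins over its internal sub-matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotation import AnnotatedText

__all__ = ["ENTITY_TYPES", "Gazetteer", "EntityMention", "load_gazetteer", "tag_entities"]

#: The closed set of recognizable entity types.
ENTITY_TYPES = frozenset(
    {
        "gene",
        "protein",
        "enzyme",
        "disease",
        "drug",
        "molecular entity",
        "organism",
        "anatomical entity",
        "cellular component",
    }
)


@dataclass(frozen=True)
class EntityMention:
    surface: str
    type: str
    token_start: int
    token_end: int
    sentence_index: int


class Gazetteer:
    """Case-insensitive surface → entity-type store (multi-token surfaces
    are keyed as token tuples)."""

    def __init__(self) -> None:
        self._by_len: dict[int, dict[tuple[str, ...], str]] = {}
        self.max_len = 0

    def add(self, surface: str, etype: str) -> None:
        if etype not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type: {etype!r}")
        key = tuple(surface.lower().split())
        if not key:
            raise ValueError("empty gazetteer surface")
        self._by_len.setdefault(len(key), {})[key] = etype
        self.max_len = max(self.max_len, len(key))

    def lookup(self, tokens: Sequence[str]) -> str | None:
        return self._by_len.get(len(tokens), {}).get(
            tuple(t.lower() for t in tokens)
        )

    def lookup_surface(self, surface: str) -> str | None:
        return self.lookup(surface.split())

    def __len__(self) -> int:
        return sum(len(d) for d in self._by_len.values())

    def surfaces(self, etype: str | None = None) -> Iterable[str]:
        for d in self._by_len.values():
            for key, t in d.items():
                if etype is None or t == etype:
                    yield " ".join(key)


def load_gazetteer(paths: Iterable[str]) -> Gazetteer:
    """Load one or more ``surface \\t type`` TSV files.

    A malformed line or an unknown type raises with the file and line
    number.  Surfaces are lowercased on load.
    """
    g = Gazetteer()
    for path in paths:
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 'surface\\ttype'")
                surface, etype = parts
                try:
                    g.add(surface, etype.strip())
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return g


def tag_entities(text: AnnotatedText, g: Gazetteer) -> list[EntityMention]:
    """Greedy longest-match left-to-right tagging over token n-grams.

    Returned mentions never overlap and are sorted by token position;
    output is invariant under case changes of the input.
    """
    mentions: list[EntityMention] = []
    if g.max_len == 0:
        return mentions
    for si, (lo, hi) in enumerate(text.sentences):
        i = lo
        while i < hi:
            matched = False
            for n in range(min(g.max_len, hi - i), 0, -1):
                span = [t.surface for t in text.tokens[i : i + n]]
                etype = g.lookup(span)
                if etype is not None:
                    mentions.append(
                        EntityMention(" ".join(span), etype, i, i + n, si)
                    )
                    i += n
                    matched = True
                    break
            if not matched:
                i += 1
    return mentions
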