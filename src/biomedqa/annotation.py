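"""Pluggable linguistic annotation: tokens, sentences, POS, lemmas, NPs.

The pipeline needs only a narrow slice of linguistic analysis — token and
sentence boundaries, coarse POS tags, lemmas, and base noun-phrase chunks —
so the annotator is an injected callable with a fully deterministic built-in
fallback (regex tokenizer, closed-class lexicon + suffix POS tagger, and a
chunk-rule NP finder).  An adapter to an industrial parser can be plugged in
through the same contract.

Also houses the morphology utilities the query builder relies on: noun
number variants, verb conjugation, nominalization lookup (a packaged
NomLEX-style verb→nominal TSV), and acronym resolution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping

__all__ = [
    "Token",
    "AnnotatedText",
    "AnnotationError",
    "annotate",
    "builtin_annotator",
    "morph_variants",
    "singularize",
    "pluralize",
    "verb_forms",
    "NominalizationLexicon",
    "load_nominalizations",
    "nominalizations",
    "resolve_acronyms",
    "normalize_np",
    "load_stopwords",
    "COPULAS",
    "AUXILIARIES",
    "WH_WORDS",
]


class AnnotationError(RuntimeError):
    """Raised when an annotator cannot produce a complete analysis."""


@dataclass(frozen=True)
class Token:
    surface: str
    lemma: str
    pos: str
    char_start: int
    char_end: int


@dataclass
class AnnotatedText:
    """Tokens, sentence spans and base-NP spans over a raw string.

    ``sentences`` and ``noun_phrases`` are half-open token-index ranges;
    every NP lies within one sentence, and token char offsets index into
    ``text`` exactly.
    """

    text: str
    tokens: list[Token]
    sentences: list[tuple[int, int]]
    noun_phrases: list[tuple[int, int]] = field(default_factory=list)

    def token_surfaces(self, lo: int | None = None, hi: int | None = None) -> list[str]:
        return [t.surface for t in self.tokens[lo:hi]]

    def np_surface(self, np_range: tuple[int, int]) -> str:
        lo, hi = np_range
        return " ".join(t.surface for t in self.tokens[lo:hi])

    def sentence_of(self, token_index: int) -> int:
        for si, (lo, hi) in enumerate(self.sentences):
            if lo <= token_index < hi:
                return si
        raise IndexError(token_index)

    def sentence_text(self, si: int) -> str:
        lo, hi = self.sentences[si]
        if lo >= hi:
            return ""
        return self.text[self.tokens[lo].char_start : self.tokens[hi - 1].char_end]


Annotator = Callable[[str], AnnotatedText]

# ---------------------------------------------------------------------------
# closed-class lexica for the fallback tagger

WH_WORDS = {"what", "which", "who", "whom", "whose", "where", "when", "why", "how"}
COPULAS = {"is", "are", "was", "were", "be", "been", "being", "am"}
AUXILIARIES = {
    "do", "does", "did", "have", "has", "had", "can", "could", "may",
    "might", "must", "shall", "should", "will", "would",
}
_DETERMINERS = {"the", "a", "an", "this", "that", "these", "those", "some", "any",
                "each", "every", "no", "both", "all", "such"}
_PREPOSITIONS = {
    "of", "in", "on", "for", "with", "to", "by", "from", "at", "as", "into",
    "between", "during", "after", "before", "about", "through", "against",
    "among", "under", "over", "without", "within", "upon", "via",
}
_CONJUNCTIONS = {"and", "or", "but", "nor"}
_PRONOUNS = {"i", "you", "he", "she", "it", "we", "they", "me", "him", "her",
             "us", "them", "its", "their", "his", "your", "my", "our"}
_ADVERBS = {"not", "also", "very", "usually", "commonly", "often", "currently",
            "mainly", "mostly", "only", "still", "yet", "too", "here", "there"}
# common verbs whose surface would otherwise default to noun
_VERB_LEXICON = {
    "diagnose", "treat", "cause", "induce", "inhibit", "relate", "report",
    "associate", "affect", "regulate", "encode", "express", "bind", "target",
    "use", "block", "activate", "suppress", "mediate", "involve", "produce",
    "increase", "decrease", "reduce", "prevent", "occur", "play", "lead",
    "result", "contain", "require", "develop", "find", "show", "indicate",
}

_ABBREVIATIONS = {"e.g", "i.e", "etc", "vs", "cf", "fig", "al", "dr", "no", "st"}

_TOKEN_RE = re.compile(
    r"[A-Za-z0-9](?:[A-Za-z0-9'’-]*[A-Za-z0-9])?|[^\sA-Za-z0-9]"
)


def _sentence_breaks(text: str, token_spans: list[tuple[int, int]]) -> list[int]:
    """Indices of tokens that end a sentence (deterministic rule set)."""
    breaks = []
    for i, (lo, hi) in enumerate(token_spans):
        tok = text[lo:hi]
        if tok not in {".", "!", "?"}:
            continue
        # abbreviation guard: previous token + "." forms a known abbreviation
        if tok == "." and i > 0:
            prev_lo, prev_hi = token_spans[i - 1]
            prev = text[prev_lo:prev_hi].lower()
            if prev in _ABBREVIATIONS or (len(prev) == 1 and prev.isalpha()):
                continue
        # must be followed by nothing, or by whitespace then an uppercase/digit
        if i + 1 < len(token_spans):
            nxt_lo = token_spans[i + 1][0]
            if nxt_lo == hi:  # no whitespace gap, e.g. "2.5"
                continue
            nxt = text[nxt_lo]
            if not (nxt.isupper() or nxt.isdigit() or nxt in "(\"'"):
                continue
        breaks.append(i)
    return breaks


def _tag(surface: str, prev_pos: str | None) -> str:
    low = surface.lower()
    if low in WH_WORDS:
        return "WRB" if low in {"where", "when", "why", "how"} else "WDT"
    if low in COPULAS or low in AUXILIARIES:
        return "MD" if low in {"can", "could", "may", "might", "must",
                               "shall", "should", "will", "would"} else "VBZ"
    if low in _DETERMINERS:
        return "DT"
    if low in _PREPOSITIONS:
        return "IN"
    if low in _CONJUNCTIONS:
        return "CC"
    if low in _PRONOUNS:
        return "PRP"
    if low == "more":
        return "RBR"
    if low == "most":
        return "RBS"
    if low in _ADVERBS or (low.endswith("ly") and len(low) > 4):
        return "RB"
    if re.fullmatch(r"\d+(\.\d+)?", low):
        return "CD"
    if not any(ch.isalnum() for ch in surface):
        return "PUNCT"
    if low in _VERB_LEXICON:
        return "VB"
    for lemma in _VERB_LEXICON:
        for form in _conjugate(lemma):
            if low == form:
                if low.endswith("ed"):
                    return "VBD"
                if low.endswith("ing"):
                    return "VBG"
                if low.endswith("s"):
                    return "VBZ"
                return "VB"
    if low.endswith("est") and len(low) > 5:
        return "JJS"
    if low.endswith(("ous", "ive", "ible", "able", "ful", "less", "ant", "ent")) and len(low) > 5:
        return "JJ"
    if low.endswith("ic") and len(low) > 4:
        return "JJ"
    if low.endswith("al") and len(low) > 5 and not low.endswith("val"):
        return "JJ"
    if low.endswith("s") and not low.endswith(("ss", "us", "is")):
        return "NNS"
    return "NN"


def _lemmatize(surface: str, pos: str) -> str:
    low = surface.lower()
    if low in COPULAS:
        return "be"
    if pos == "NNS":
        return singularize(low)
    if pos.startswith("VB") and pos != "VB":
        for lemma in _VERB_LEXICON:
            if low in _conjugate(lemma):
                return lemma
        if low.endswith("ing") and len(low) > 5:
            stem = low[:-3]
            return stem + "e" if not stem.endswith(("e", "y")) else stem
        if low.endswith("ed") and len(low) > 4:
            return low[:-1] if low[:-1].endswith("e") else low[:-2]
        if low.endswith("s") and not low.endswith("ss"):
            return low[:-1]
    return low


def builtin_annotator(text: str) -> AnnotatedText:
    """Deterministic fallback: regex tokenizer, lexicon+suffix tagger,
    rule-based sentence splitter and base-NP chunker."""
    if not text or not text.strip():
        raise AnnotationError("cannot annotate empty text")
    spans = [(m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
    tokens: list[Token] = []
    prev_pos: str | None = None
    for lo, hi in spans:
        surf = text[lo:hi]
        pos = _tag(surf, prev_pos)
        tokens.append(Token(surf, _lemmatize(surf, pos), pos, lo, hi))
        prev_pos = pos

    breaks = _sentence_breaks(text, spans)
    sentences: list[tuple[int, int]] = []
    start = 0
    for b in breaks:
        sentences.append((start, b + 1))
        start = b + 1
    if start < len(tokens):
        sentences.append((start, len(tokens)))
    if not sentences:
        sentences = [(0, len(tokens))]

    noun_phrases = _chunk_nps(tokens, sentences)
    return AnnotatedText(text, tokens, sentences, noun_phrases)


_NP_INNER = {"DT", "JJ", "JJR", "JJS", "CD", "NN", "NNS", "VBG"}
_NP_HEAD = {"NN", "NNS"}


def _chunk_nps(tokens: list[Token], sentences: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Base (non-recursive) NP chunks: maximal runs of determiner/adjective/
    cardinal/noun tokens that end in a noun, per sentence."""
    nps: list[tuple[int, int]] = []
    for lo, hi in sentences:
        i = lo
        while i < hi:
            if tokens[i].pos in _NP_INNER:
                j = i
                while j < hi and tokens[j].pos in _NP_INNER:
                    j += 1
            # trim trailing non-head tokens
                k = j
                while k > i and tokens[k - 1].pos not in _NP_HEAD:
                    k -= 1
                if k > i and any(tokens[m].pos in _NP_HEAD for m in range(i, k)):
                    nps.append((i, k))
                i = j
            else:
                i += 1
    return nps


def annotate(text: str, annotator: Annotator | None = None) -> AnnotatedText:
    """Annotate ``text`` with the injected annotator (built-in by default).

    Any annotator failure surfaces as :class:`AnnotationError`; a partial
    result is never returned.
    """
    fn = annotator or builtin_annotator
    try:
        ann = fn(text)
    except AnnotationError:
        raise
    except Exception as exc:  # noqa: BLE001 — contract: typed error only
        raise AnnotationError(f"annotator failed: {exc}") from exc
    for tok in ann.tokens:
        if ann.text[tok.char_start : tok.char_end] != tok.surface:
            raise AnnotationError("token char offsets do not index the text")
    return ann


# ---------------------------------------------------------------------------
# morphology

_IRREGULAR_PLURALS = {
    "child": "children", "man": "men", "woman": "women", "foot": "feet",
    "tooth": "teeth", "mouse": "mice", "bacterium": "bacteria",
    "fungus": "fungi", "nucleus": "nuclei", "stimulus": "stimuli",
    "genus": "genera", "datum": "data", "criterion": "criteria",
    "phenomenon": "phenomena", "analysis": "analyses", "hypothesis": "hypotheses",
}
_IRREGULAR_SINGULARS = {v: k for k, v in _IRREGULAR_PLURALS.items()}

_UNCOUNTABLE = {"species", "series", "fish", "deer", "dna", "rna", "data"}


def pluralize(noun: str) -> str:
    low = noun.lower()
    if low in _UNCOUNTABLE or low in _IRREGULAR_SINGULARS:
        return low if low in _UNCOUNTABLE else low
    if low in _IRREGULAR_PLURALS:
        return _IRREGULAR_PLURALS[low]
    if low.endswith("is"):
        return low[:-2] + "es"  # craniosynostosis -> craniosynostoses
    if low.endswith(("s", "x", "z", "ch", "sh")):
        return low + "es"
    if low.endswith("y") and len(low) > 1 and low[-2] not in "aeiou":
        return low[:-1] + "ies"
    return low + "s"


def singularize(noun: str) -> str:
    low = noun.lower()
    if low in _UNCOUNTABLE:
        return low
    if low in _IRREGULAR_SINGULARS:
        return _IRREGULAR_SINGULARS[low]
    if low.endswith("ies") and len(low) > 4:
        return low[:-3] + "y"
    if low.endswith(("ches", "shes", "xes", "zes", "sses")):
        return low[:-2]
    if low.endswith("oses") or low.endswith("yses"):
        return low[:-2] + "is"  # craniosynostoses -> craniosynostosis
    if low.endswith("s") and not low.endswith(("ss", "us", "is")):
        return low[:-1]
    return low


def morph_variants(surface: str) -> set[str]:
    """Singular and plural forms of a noun or NP (head-token inflection).

    Idempotent: applying it to any of its outputs adds nothing new.
    """
    toks = surface.lower().split()
    head = toks[-1]
    sing, plur = singularize(head), pluralize(singularize(head))
    prefix = " ".join(toks[:-1])
    out = set()
    for h in {sing, plur}:
        out.add((prefix + " " + h).strip())
    return out


def _conjugate(lemma: str) -> set[str]:
    low = lemma.lower()
    third = pluralize(low) if not low.endswith(("s", "sh", "ch", "x", "z", "o")) else low + "es"
    if low.endswith("y") and len(low) > 1 and low[-2] not in "aeiou":
        third = low[:-1] + "ies"
        past = low[:-1] + "ied"
        gerund = low + "ing"
    elif low.endswith("e") and not low.endswith("ee"):
        third = low + "s"
        past = low + "d"
        gerund = low[:-1] + "ing"
    else:
        third = low + "s"
        past = low + "ed"
        gerund = low + "ing"
    return {low, third, past, gerund}


def verb_forms(lemma: str) -> set[str]:
    """Infinitive plus 3rd-singular, past, and gerund forms of a verb lemma."""
    return _conjugate(lemma)


# ---------------------------------------------------------------------------
# nominalizations

NominalizationLexicon = Mapping[str, set]


def load_nominalizations(path: str | None = None) -> dict[str, set[str]]:
    """Load a verb→nominal TSV; defaults to the packaged lexicon."""
    if path is None:
        ref = resources.files("biomedqa.data").joinpath("nominalizations.tsv")
        content = ref.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            content = fh.read()
    lex: dict[str, set[str]] = {}
    for line in content.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        verb, *noms = line.split("\t")
        lex.setdefault(verb.strip().lower(), set()).update(
            n.strip().lower() for n in noms if n.strip()
        )
    return lex


def nominalizations(verb_lemma: str, lexicon: NominalizationLexicon) -> set[str]:
    """Nominal forms of a verb lemma, or the empty set when unmapped."""
    return set(lexicon.get(verb_lemma.lower(), set()))


def load_stopwords() -> frozenset[str]:
    ref = resources.files("biomedqa.data").joinpath("stopwords.txt")
    return frozenset(
        w.strip().lower()
        for w in ref.read_text(encoding="utf-8").splitlines()
        if w.strip()
    )


# ---------------------------------------------------------------------------
# acronyms

_ACRO_RE = re.compile(r"\(\s*([A-Z][A-Za-z0-9 .\-]{0,12}?)\s*\)")


def _schwartz_hearst(short: str, candidate: str) -> str | None:
    """Map an acronym onto the shortest preceding span whose word-initial
    characters account for it (the standard abbreviation-definition
    alignment: match characters right-to-left, anchoring the first character
    at a word start)."""
    s = [c for c in short.lower() if c.isalnum()]
    l = candidate.lower()
    si = len(s) - 1
    li = len(l) - 1
    while si >= 0:
        c = s[si]
        while li >= 0 and (
            l[li] != c
            or (si == 0 and li > 0 and l[li - 1].isalnum())
        ):
            li -= 1
        if li < 0:
            return None
        si -= 1
        li -= 1
    # expansion starts at the word containing position li+1
    start = l.rfind(" ", 0, li + 2) + 1
    return candidate[start:].strip() or None


def resolve_acronyms(
    question: AnnotatedText, table: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Acronym → expansion mappings for a question.

    Detects (i) parenthetical definitions inside the question text and
    (ii) lookups in the supplied table, in both directions (acronym →
    expansion when the acronym occurs; NP → its acronym when the expansion
    occurs).
    """
    table = {k: v for k, v in (table or {}).items()}
    out: dict[str, str] = {}

    for m in _ACRO_RE.finditer(question.text):
        short = m.group(1).strip()
        if not any(c.isupper() for c in short):
            continue
        before = question.text[: m.start()].strip()
        # candidate span: up to ~2x acronym length + 5 words back
        words = before.split()
        n = min(len(words), 2 * len([c for c in short if c.isalnum()]) + 5)
        candidate = " ".join(words[-n:])
        exp = _schwartz_hearst(short, candidate)
        if exp:
            out[short] = exp

    if table:
        lower_table = {k.lower(): (k, v) for k, v in table.items()}
        reverse = {v.lower(): (k, v) for k, v in table.items()}
        text_low = question.text.lower()
        for tok in question.tokens:
            hit = lower_table.get(tok.surface.lower())
            if hit and hit[0] not in out:
                out[hit[0]] = hit[1]
        for np in question.noun_phrases:
            surf = question.np_surface(np).lower()
            hit = reverse.get(surf)
            if hit and hit[0] not in out:
                out[hit[0]] = hit[1]
    return out


# ---------------------------------------------------------------------------
# NP normalization

_NP_DROP_LEAD = _DETERMINERS | _PRONOUNS | {"more", "most"}


def normalize_np(surface: str) -> str:
    """Normalize an NP for search: drop leading articles, pronouns, gerund
    modifiers, comparatives/superlatives, and possessive markers."""
    toks = surface.replace("’", "'").split()
    while toks and (
        toks[0].lower() in _NP_DROP_LEAD
        or toks[0].lower().endswith("est") and len(toks[0]) > 5 and len(toks) > 1
        or (toks[0].lower().endswith("ing") and len(toks) > 1 and len(toks[0]) > 5)
    ):
        toks = toks[1:]
    out = []
    for t in toks:
        t = re.sub(r"'s$|'$", "", t)
        if t:
            out.append(t)
    return " ".join(out)
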