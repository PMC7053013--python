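"""Question analysis: wh-word, question type, focus phrase, candidate terms.

A question's *focus* is the noun phrase naming the semantic type of its
expected answer ("Which membrane protein ..." → "membrane protein").  The
focus drives two decisions downstream: answer sentences can be filtered by
the focus entity type, and the focus is protected during query relaxation.

Candidate search terms are everything the retrieval stage may put into the
boolean keyword query: non-copula verbs with their conjugations and
nominalizations, normalized NPs with number variants and acronym
expansions, each NP's individual words, and vocabulary-validated
subphrases.  Every term carries an IDF weight from the corpus lexicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .annotation import (
    AUXILIARIES,
    AnnotatedText,
    COPULAS,
    WH_WORDS,
    annotate,
    morph_variants,
    nominalizations,
    normalize_np,
    resolve_acronyms,
    verb_forms,
)
from .gazetteer import Gazetteer
from .lexicon import Lexicon

__all__ = [
    "AnalyzedQuestion",
    "CandidateTerm",
    "DEFAULT_FOCUS_TRIGGERS",
    "analyze_question",
    "detect_question_type",
    "detect_focus",
    "generate_candidate_terms",
    "enumerate_subphrases",
]

#: head-noun → entity-type trigger table (configurable; singular heads,
#: number variants matched through singularization)
DEFAULT_FOCUS_TRIGGERS: dict[str, str] = {
    "gene": "gene",
    "protein": "protein",
    "enzyme": "enzyme",
    "disease": "disease",
    "disorder": "disease",
    "syndrome": "disease",
    "drug": "drug",
    "medication": "drug",
    "compound": "molecular entity",
    "molecule": "molecular entity",
    "organism": "organism",
    "species": "organism",
    "bacterium": "organism",
    "virus": "organism",
    "organ": "anatomical entity",
    "tissue": "anatomical entity",
    "organelle": "cellular component",
}


@dataclass
class AnalyzedQuestion:
    annotated: AnnotatedText
    wh_word: str | None
    question_type: str  # definition | focus | other
    focus_phrase: str | None
    focus_modifiers: list[str] = field(default_factory=list)
    focus_entity_type: str | None = None


@dataclass(frozen=True)
class CandidateTerm:
    surface: str
    kind: str  # verb | np | np_word | subphrase | entity | expansion
    weight: float
    variant_of: str | None = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        if self.kind == "expansion" and self.variant_of is None:
            raise ValueError("expansion terms must record their parent surface")


def _wh_index(ann: AnnotatedText) -> int | None:
    for i, tok in enumerate(ann.tokens):
        if tok.surface.lower() in WH_WORDS:
            return i
    return None


def _first_np_after(ann: AnnotatedText, idx: int) -> tuple[int, int] | None:
    for lo, hi in ann.noun_phrases:
        if lo >= idx:
            return (lo, hi)
    return None


def _np_following_token(ann: AnnotatedText, tok_idx: int) -> tuple[int, int] | None:
    for lo, hi in ann.noun_phrases:
        if lo == tok_idx:
            return (lo, hi)
    return None


def detect_focus(ann: AnnotatedText) -> tuple[str | None, list[str]]:
    """Locate the focus NP and any prepositional modifier NPs.

    Rule precedence: the NP immediately after the wh-word; else, when a
    copula/auxiliary directly follows the wh-word, the first NP after that
    verb; when the found NP is followed by "of"/"in" plus an NP, the
    post-preposition NP becomes the focus and the pre-preposition NP its
    modifier.  The returned phrase is normalized (articles, possessives,
    comparatives/superlatives stripped) and never contains the wh-word.
    """
    wh = _wh_index(ann)
    if wh is None:
        return None, []
    focus_range = None
    nxt = wh + 1
    # NP starting right at the wh-word's successor (wh-adjacent)
    adjacent = _np_following_token(ann, nxt)
    if adjacent is not None:
        focus_range = adjacent
    elif nxt < len(ann.tokens) and ann.tokens[nxt].surface.lower() in (COPULAS | AUXILIARIES):
        focus_range = _first_np_after(ann, nxt + 1)
    else:
        focus_range = _first_np_after(ann, nxt)
    if focus_range is None:
        return None, []

    modifiers: list[str] = []
    lo, hi = focus_range
    # prepositional attachment: NP of/in NP → post-prep NP is the focus
    if hi < len(ann.tokens) and ann.tokens[hi].surface.lower() in {"of", "in"}:
        post = _np_following_token(ann, hi + 1)
        if post is not None:
            mod = normalize_np(ann.np_surface((lo, hi)))
            if mod:
                modifiers.append(mod)
            lo, hi = post

    focus = normalize_np(ann.np_surface((lo, hi)))
    return (focus or None), modifiers


def _has_content_verb(ann: AnnotatedText) -> bool:
    skip = COPULAS | AUXILIARIES
    return any(
        t.pos.startswith("VB") and t.surface.lower() not in skip
        for t in ann.tokens
    )


def _has_degree_marker(ann: AnnotatedText) -> bool:
    return any(t.pos in {"RBS", "RBR", "JJS", "JJR"} for t in ann.tokens)


def detect_question_type(ann: AnnotatedText) -> str:
    """Classify as definition ("what is/are X" with no further predicate),
    focus (a focus NP is found), or other (e.g. yes/no questions)."""
    wh = _wh_index(ann)
    if wh is None:
        return "other"
    toks = ann.tokens
    if (
        toks[wh].surface.lower() == "what"
        and wh + 1 < len(toks)
        and toks[wh + 1].surface.lower() in COPULAS
        and not _has_content_verb(ann)
        and not _has_degree_marker(ann)
    ):
        return "definition"
    focus, _ = detect_focus(ann)
    return "focus" if focus else "other"


def analyze_question(
    text: str,
    annotator=None,
    focus_triggers: Mapping[str, str] | None = None,
    gazetteer: Gazetteer | None = None,
) -> AnalyzedQuestion:
    """Annotate a question string and derive wh-word, type and focus."""
    if not text or not text.strip():
        raise ValueError("empty question")
    ann = annotate(text, annotator)
    wh = _wh_index(ann)
    wh_word = ann.tokens[wh].surface.lower() if wh is not None else None
    focus, modifiers = detect_focus(ann) if wh is not None else (None, [])
    qtype = detect_question_type(ann)

    etype: str | None = None
    if focus:
        triggers = dict(DEFAULT_FOCUS_TRIGGERS if focus_triggers is None else focus_triggers)
        from .annotation import singularize

        head = singularize(focus.split()[-1].lower())
        etype = triggers.get(head)
        if etype is None and gazetteer is not None:
            etype = gazetteer.lookup_surface(focus)
    return AnalyzedQuestion(ann, wh_word, qtype, focus, modifiers, etype)


def enumerate_subphrases(np_surface: str, vocabulary: Lexicon) -> set[str]:
    """Sub-spans of an NP validated against the vocabulary.

    Dropping words repeatedly from either end reaches every contiguous
    sub-span, so all proper sub-spans of length ≥ 2 found in the vocabulary
    are returned, plus each individual word.
    """
    toks = np_surface.lower().split()
    out: set[str] = set(toks)
    n = len(toks)
    for length in range(2, n):
        for i in range(n - length + 1):
            cand = " ".join(toks[i : i + length])
            if cand in vocabulary:
                out.add(cand)
    return out


_SKIP_WORDS = COPULAS | AUXILIARIES


def generate_candidate_terms(
    q: AnalyzedQuestion,
    lexicon: Lexicon,
    nominalization_lexicon: Mapping[str, set] | None = None,
    acronym_table: Mapping[str, str] | None = None,
    stopwords: frozenset[str] = frozenset(),
) -> list[CandidateTerm]:
    """Weighted candidate search terms for a question.

    Emits non-copula verbs (conjugations and nominalizations as
    expansions), normalized NPs (number variants and acronym expansions as
    expansions), each NP's individual words, and vocabulary-validated
    subphrases.  Weights are corpus IDF; out-of-vocabulary surfaces get the
    maximum observed IDF so rare biomedical terms are retained
    preferentially.  Duplicate surfaces keep the maximum weight.
    """
    ann = q.annotated
    max_idf = lexicon.max_idf()

    def weight(surface: str) -> float:
        return lexicon.idf(surface, default=max_idf)

    acc: dict[str, CandidateTerm] = {}

    def emit(surface: str, kind: str, variant_of: str | None = None) -> None:
        surface = surface.lower().strip()
        if not surface or surface in stopwords:
            return
        term = CandidateTerm(surface, kind, weight(surface), variant_of)
        prev = acc.get(surface)
        if prev is None or term.weight > prev.weight:
            # keep the earlier kind when the new one is only an expansion
            if prev is not None and term.kind == "expansion":
                term = CandidateTerm(surface, prev.kind, term.weight, prev.variant_of)
            acc[surface] = term

    # verbs (non-copula/auxiliary)
    for tok in ann.tokens:
        if tok.pos.startswith("VB") and tok.surface.lower() not in _SKIP_WORDS:
            lemma = tok.lemma
            emit(lemma, "verb")
            for form in verb_forms(lemma):
                if form != lemma:
                    emit(form, "expansion", variant_of=lemma)
            if nominalization_lexicon:
                for nom in nominalizations(lemma, nominalization_lexicon):
                    emit(nom, "expansion", variant_of=lemma)

    # NPs with number variants, acronym expansions, words, subphrases
    acronyms = resolve_acronyms(ann, acronym_table)
    for np_range in ann.noun_phrases:
        raw = ann.np_surface(np_range)
        np = normalize_np(raw).lower()
        if not np or np in stopwords:
            continue
        emit(np, "np")
        for var in morph_variants(np):
            if var != np:
                emit(var, "expansion", variant_of=np)
        for acro, expansion in acronyms.items():
            if acro.lower() == np or expansion.lower() == np:
                other = expansion if acro.lower() == np else acro
                emit(other, "expansion", variant_of=np)
        toks = np.split()
        if len(toks) > 1:
            for sub in enumerate_subphrases(np, lexicon):
                if sub == np:
                    continue
                kind = "np_word" if " " not in sub else "subphrase"
                emit(sub, kind)
    return list(acc.values())
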