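"""Synthetic corpus/embedding/gazetteer/gold fixtures for offline testing.

Everything here is synthetic: invented entity names ("zelorafenib",
"bmrx4"), invented abstracts, and embeddings constructed from shared
latent topic directions rather than trained on text.  The construction
guarantees that each planted question's answer sentence contains the
question's content terms exactly (so its similarity score is maximal) while
distractor documents use near-orthogonal topic directions — the planted
answers are uniquely optimal for the ranking stage, which makes end-to-end
recovery a deterministic property rather than a statistical hope.

Generation is fully seeded: the same spec writes byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .lexicon import EmbeddingStore, tokenize_simple
from .retrieval import DocumentRecord, write_corpus_jsonl

__all__ = [
    "PlantedQA",
    "FixtureSpec",
    "Fixture",
    "generate_fixture",
    "DEFAULT_PLANTED",
    "generate_selector_dataset",
    "generate_reranker_dataset",
]


@dataclass(frozen=True)
class PlantedQA:
    question: str
    answer_sentence: str
    answer_entity: str
    entity_type: str
    content_terms: tuple[str, ...]  # discriminative terms shared Q <-> A


DEFAULT_PLANTED: tuple[PlantedQA, ...] = (
    PlantedQA(
        "Which drug inhibits neurodegeneration?",
        "The drug zelorafenib inhibits neurodegeneration in cortical neurons.",
        "zelorafenib", "drug", ("drug", "inhibits", "neurodegeneration"),
    ),
    PlantedQA(
        "Which gene regulates osteogenesis?",
        "The gene bmrx4 regulates osteogenesis during skeletal development.",
        "bmrx4", "gene", ("gene", "regulates", "osteogenesis"),
    ),
    PlantedQA(
        "Which protein binds collagen?",
        "The protein fibrokinin binds collagen in the extracellular matrix.",
        "fibrokinin", "protein", ("protein", "binds", "collagen"),
    ),
    PlantedQA(
        "Which disease causes ataxia?",
        "The disease spinotaxia causes ataxia in affected families.",
        "spinotaxia", "disease", ("disease", "causes", "ataxia"),
    ),
    PlantedQA(
        "Which organism produces levostatin?",
        "The organism terricola produces levostatin under nutrient stress.",
        "terricola", "organism", ("organism", "produces", "levostatin"),
    ),
)

_DISTRACTOR_TOPICS = [
    ("membrane", "transport", "vesicle", "gradient"),
    ("kinase", "phosphorylation", "substrate", "cascade"),
    ("tumor", "angiogenesis", "microenvironment", "hypoxia"),
    ("microbiome", "colonization", "mucosa", "commensal"),
    ("receptor", "ligand", "affinity", "conformation"),
    ("mitochondria", "respiration", "oxidation", "flux"),
    ("antibody", "epitope", "neutralization", "titer"),
    ("chromatin", "methylation", "silencing", "locus"),
    ("synapse", "plasticity", "potentiation", "dendrite"),
    ("fibrosis", "scarring", "myofibroblast", "remodeling"),
]

_EXTRA_ENTITY_STEMS = {
    "drug": "drugexin",
    "gene": "genrx",
    "protein": "proteolin",
    "disease": "malacosis",
    "organism": "bacillux",
    "enzyme": "enzymase",
    "molecular entity": "moleculin",
    "anatomical entity": "anatomon",
    "cellular component": "cellosome",
}


@dataclass
class FixtureSpec:
    n_docs: int = 50
    embedding_dim: int = 32
    seed: int = 0
    n_gazetteer_per_type: int = 8
    planted: tuple[PlantedQA, ...] = DEFAULT_PLANTED

    def __post_init__(self) -> None:
        if self.n_docs < len(self.planted) or self.n_docs < 1:
            raise ValueError("n_docs must cover at least the planted QA pairs")
        if self.embedding_dim < len(self.planted) + len(_DISTRACTOR_TOPICS) + 2:
            raise ValueError("embedding_dim too small for orthogonal topics")


@dataclass
class Fixture:
    corpus_path: str
    embeddings_path: str
    gazetteer_path: str
    gold_path: str
    docs: list[DocumentRecord] = field(default_factory=list)
    spec: FixtureSpec | None = None


def _topic_vector(rng: np.random.Generator, dim: int, axis: int) -> np.ndarray:
    v = np.zeros(dim)
    v[axis] = 1.0
    return v


def generate_fixture(spec: FixtureSpec, out_dir: str) -> Fixture:
    """Write corpus JSONL, GloVe-format embeddings, gazetteer TSV and a
    BioASQ-style gold JSON under ``out_dir``; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    os.makedirs(out_dir, exist_ok=True)

    docs: list[DocumentRecord] = []
    word_topic: dict[str, int] = {}

    # planted answer documents: one per QA pair, topic axis = pair index
    for i, qa in enumerate(spec.planted):
        title = f"Studies of {qa.content_terms[-1]}."
        tail = f"These observations clarify the role of {qa.content_terms[-1]}."
        docs.append(DocumentRecord(f"doc{i:04d}", title, qa.answer_sentence + " " + tail))
        for tok in tokenize_simple(qa.question + " " + qa.answer_sentence):
            word_topic.setdefault(tok, i)

    # distractor documents from orthogonal topics
    n_planted = len(spec.planted)
    for j in range(n_planted, spec.n_docs):
        topic_idx = (j - n_planted) % len(_DISTRACTOR_TOPICS)
        words = _DISTRACTOR_TOPICS[topic_idx]
        a, b, c, d = words
        variant = (j - n_planted) // len(_DISTRACTOR_TOPICS)
        title = f"Analysis of {a} {b}."
        abstract = (
            f"The {a} {b} was examined in {c} models. "
            f"Changes in {d} were observed across replicate {variant} series."
        )
        docs.append(DocumentRecord(f"doc{j:04d}", title, abstract))
        axis = n_planted + topic_idx
        for tok in tokenize_simple(title + " " + abstract):
            word_topic.setdefault(tok, axis)

    corpus_path = os.path.join(out_dir, "corpus.jsonl")
    write_corpus_jsonl(docs, corpus_path)

    # embeddings: topic direction + small seeded idiosyncratic noise
    store = EmbeddingStore(spec.embedding_dim)
    for word in sorted(word_topic):
        axis = word_topic[word]
        noise = rng.normal(0, 0.05, spec.embedding_dim)
        store.add(word, _topic_vector(rng, spec.embedding_dim, axis) + noise)
    embeddings_path = os.path.join(out_dir, "embeddings.txt")
    store.save(embeddings_path)

    # gazetteer: planted entities plus synthetic padding names per type
    gazetteer_path = os.path.join(out_dir, "gazetteer.tsv")
    with open(gazetteer_path, "w", encoding="utf-8") as fh:
        fh.write("# synthetic gazetteer fixture\n")
        for qa in spec.planted:
            fh.write(f"{qa.answer_entity}\t{qa.entity_type}\n")
        for etype, stem in _EXTRA_ENTITY_STEMS.items():
            for k in range(spec.n_gazetteer_per_type):
                fh.write(f"{stem}{k}\t{etype}\n")

    gold_path = os.path.join(out_dir, "gold.json")
    payload = {
        "questions": [
            {
                "id": f"q{i}",
                "body": qa.question,
                "type": "factoid",
                "exact_answer": [qa.answer_entity],
                "ideal_answer": [qa.answer_sentence],
            }
            for i, qa in enumerate(spec.planted)
        ]
    }
    with open(gold_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)

    return Fixture(corpus_path, embeddings_path, gazetteer_path, gold_path, docs, spec)


def generate_selector_dataset(
    n_questions: int = 500,
    embedding_dim: int = 20,
    seed: int = 0,
    n_content: int = 60,
    n_filler: int = 50,
    n_blocker: int = 10,
):
    """Planted-rule keyword-selection dataset.

    Tokens come from a content lexicon (query-worthy terms), a filler
    lexicon, and a small set of blocker markers; a token is a keyword iff
    its content status XOR whether the previous token is a blocker.  The
    contextual override makes the rule unlearnable from a token in
    isolation, so architectures that see context (recurrent encoders)
    separate from those that do not — while keeping the rule exactly
    recoverable.  Embeddings carry the content and blocker indicators as
    latent coordinates plus seeded noise.

    Returns (encoded questions, embedding store).
    """
    from .selector import encode_question

    rng = np.random.default_rng(seed)
    vocab = (
        [f"term{i}" for i in range(n_content)]
        + [f"fill{i}" for i in range(n_filler)]
        + [f"blk{i}" for i in range(n_blocker)]
    )
    V = len(vocab)
    is_content = np.arange(V) < n_content
    is_blocker = np.arange(V) >= n_content + n_filler

    store = EmbeddingStore(embedding_dim)
    base = rng.normal(0, 0.3, (V, embedding_dim))
    base[:, 0] = np.where(is_content, 1.0, -1.0)
    base[:, 1] = np.where(is_blocker, 1.0, -1.0)
    for i, w in enumerate(vocab):
        store.add(w, base[i])

    encoded = []
    for _ in range(n_questions):
        length = int(rng.integers(5, 24))
        idx = rng.integers(0, V, length)
        tokens = [vocab[i] for i in idx]
        prev_blocker = np.zeros(length, dtype=bool)
        prev_blocker[1:] = is_blocker[idx[:-1]]
        labels = (is_content[idx] ^ prev_blocker).astype(int)
        encoded.append(encode_question(tokens, store, labels))
    return encoded, store


def generate_reranker_dataset(
    n_questions: int = 60,
    pool_size: int = 20,
    embedding_dim: int = 16,
    seed: int = 0,
):
    """Separable sentence-pair reranking dataset with a planted answer cue.

    Every correct answer sentence contains the marker token "answerine";
    incorrect pool members never do.  Returns (judged runs, embedding
    store): each run's candidates are in a random order with the correct
    sentence's position recorded, emulating a baseline ranking whose first
    correct answer sits at an arbitrary rank.
    """
    from .reranker import JudgedRun

    rng = np.random.default_rng(seed)
    vocab = [f"tok{i}" for i in range(50)]
    store = EmbeddingStore(embedding_dim)
    for w in vocab:
        store.add(w, rng.normal(0, 1.0, embedding_dim))
    # the marker must dominate the mean-pooled sentence vector for the
    # pairs to be genuinely separable
    marker = np.zeros(embedding_dim)
    marker[0] = 8.0
    store.add("answerine", marker + rng.normal(0, 0.05, embedding_dim))

    runs = []
    for qi in range(n_questions):
        q_words = rng.choice(vocab, 5, replace=False)
        question = "what does " + " ".join(q_words) + " do?"
        positive = " ".join(rng.choice(vocab, 4, replace=False)) + " answerine effect."
        negatives = [
            " ".join(rng.choice(vocab, 5, replace=False)) + "."
            for _ in range(pool_size - 1)
        ]
        pos_rank = int(rng.integers(1, pool_size + 1))
        pool = negatives[: pos_rank - 1] + [positive] + negatives[pos_rank - 1 :]
        runs.append(JudgedRun(question, tuple(pool), pos_rank))
    return runs, store
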