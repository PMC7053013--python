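import numpy as np
import pytest

from biomedqa.fixtures import FixtureSpec, generate_fixture
from biomedqa.lexicon import EmbeddingStore, Lexicon, VocabEntry
from biomedqa.pipeline import PipelineConfig, QAPipeline


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    return generate_fixture(FixtureSpec(seed=1), str(out))


@pytest.fixture(scope="session")
def planted_pipeline(fixture_dir):
    cfg = PipelineConfig(
        corpus_path=fixture_dir.corpus_path,
        embeddings_path=fixture_dir.embeddings_path,
        gazetteer_paths=(fixture_dir.gazetteer_path,),
    )
    return QAPipeline.from_config(cfg)


def make_lexicon(weights: dict[str, float], n_docs: int = 100) -> Lexicon:
    """Lexicon with prescribed IDF weights (doc frequencies back-computed)."""
    import math

    entries = []
    for surface, idf in weights.items():
        df = max(1, round(n_docs / math.exp(idf)))
        entries.append(VocabEntry(surface, df, idf))
    return Lexicon(entries, n_docs)


def make_embeddings(vectors: dict[str, list[float]]) -> EmbeddingStore:
    dim = len(next(iter(vectors.values())))
    store = EmbeddingStore(dim)
    for s, v in vectors.items():
        store.add(s, v)
    return store


def random_embeddings(surfaces, dim, rng) -> EmbeddingStore:
    store = EmbeddingStore(dim)
    for s in surfaces:
        store.add(s, rng.normal(size=dim))
    return store
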