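import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_corpus():
    """Six hand-written documents with two clear topics."""
    from misinfonet.corpus import Document

    return [
        Document(id="d1", text="Vaccines are safe and effective", label="trustworthy"),
        Document(id="d2", text="Wash your hands to prevent infection", label="trustworthy"),
        Document(id="d3", text="Masks reduce viral transmission indoors", label="trustworthy"),
        Document(id="d4", text="5G towers spread the coronavirus", label="misinformation"),
        Document(id="d5", text="Drinking bleach cures the virus", label="misinformation"),
        Document(id="d6", text="The vaccine contains tracking microchips", label="misinformation"),
    ]


@pytest.fixture(scope="session")
def separable_corpus():
    """Synthetic balanced separable corpus shared across model tests."""
    from misinfonet.preprocess import clean_corpus
    from misinfonet.synth import CorpusSpec, generate_corpus

    spec = CorpusSpec(
        n_docs=400,
        minority_fraction=0.5,
        topic_purity=0.95,
        cross_topic_rate=0.0,
        doc_length_range=(8, 20),
        seed=7,
    )
    docs, _ = generate_corpus(spec)
    toks = clean_corpus(docs)
    y = np.array([1 if d.label == "misinformation" else 0 for d in docs])
    return docs, toks, y
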