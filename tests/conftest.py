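import numpy as np
import pytest

from lsnb import Document, SyntheticCorpusSpec, Vocabulary, generate_corpus


@pytest.fixture
def casino_docs() -> list[Document]:
    """Three-document fixture with hand-computable statistics."""
    return [
        Document("casino casino money".split(), "spam", "s0"),
        Document("casino money".split(), "spam", "s1"),
        Document("meeting money".split(), "ham", "h0"),
    ]


@pytest.fixture
def casino_vocab() -> Vocabulary:
    return Vocabulary(["casino", "money"])


def random_tables(n: int, seed: int, low: float = 0.0, high: float = 1.0):
    """Valid random contingency tables (cells uniform, never all zero)."""
    rng = np.random.default_rng(seed)
    cells = rng.uniform(low, high, size=(n, 4))
    keep = cells.sum(axis=1) > 0
    return cells[keep]


@pytest.fixture
def fifty_doc_corpus() -> list[Document]:
    """Moderately noisy 50-document corpus for oracle comparisons."""
    spec = SyntheticCorpusSpec(
        n_spam=20, n_ham=30, shared_vocab_size=15,
        spam_vocab_size=4, ham_vocab_size=4,
        discriminative_strength=0.6, doc_length=20.0, burstiness=1.0, seed=123,
    )
    return generate_corpus(spec)
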