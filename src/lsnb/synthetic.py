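"""Seeded two-class synthetic corpus generation.

Emulates the statistical structure the classifiers assume: two classes with
a shared background vocabulary, class-exclusive discriminative words, and
bursty within-document repetition of content words (so content words tend
to be observed more than once and survive the min-count vocabulary filter).

Word strings are lowercase alphabetic identifiers (``saaa``/``haaa``/
``caaa`` for spam-exclusive / ham-exclusive / common words) so the default
cleaning pipeline passes them through untouched.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .preprocessing import Document

__all__ = ["SyntheticCorpusSpec", "generate_corpus"]


def _word_id(prefix: str, i: int, width: int = 3) -> str:
    """Letters-only identifier: stop-word filtering and digit stripping stay inert."""
    letters = []
    for _ in range(width):
        i, r = divmod(i, 26)
        letters.append(string.ascii_lowercase[r])
    return prefix + "".join(reversed(letters))


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Generator parameters.

    ``discriminative_strength`` is the probability that each class-exclusive
    word appears in a document of its own class; exclusive words never
    appear in the other class.  ``burstiness`` sets the mean number of extra
    repetitions of each present word (geometric), and ``doc_length`` the
    target mean token count per document, achieved in expectation by tuning
    the presence probability of shared words.
    """

    n_spam: int
    n_ham: int
    shared_vocab_size: int = 20
    spam_vocab_size: int = 5
    ham_vocab_size: int = 5
    discriminative_strength: float = 1.0
    doc_length: float = 30.0
    burstiness: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_spam, self.n_ham) < 0:
            raise ValueError("document counts must be >= 0")
        if min(self.shared_vocab_size, self.spam_vocab_size, self.ham_vocab_size) < 0:
            raise ValueError("vocabulary sizes must be >= 0")
        if not 0.0 <= self.discriminative_strength <= 1.0:
            raise ValueError("discriminative_strength must be in [0, 1]")
        if self.burstiness < 0:
            raise ValueError("burstiness must be >= 0")
        if self.doc_length <= 0:
            raise ValueError("doc_length must be > 0")

    @property
    def spam_words(self) -> tuple[str, ...]:
        return tuple(_word_id("s", i) for i in range(self.spam_vocab_size))

    @property
    def ham_words(self) -> tuple[str, ...]:
        return tuple(_word_id("h", i) for i in range(self.ham_vocab_size))

    @property
    def shared_words(self) -> tuple[str, ...]:
        return tuple(_word_id("c", i) for i in range(self.shared_vocab_size))

    @property
    def shared_presence_prob(self) -> float:
        """Presence probability of each shared word, tuned so the expected
        document length matches ``doc_length``."""
        if self.shared_vocab_size == 0:
            return 0.0
        mean_reps = 1.0 + self.burstiness
        excl = self.discriminative_strength * max(self.spam_vocab_size, self.ham_vocab_size)
        target_present = self.doc_length / mean_reps - excl
        return float(np.clip(target_present / self.shared_vocab_size, 0.02, 1.0))


def _repeat_counts(rng: np.random.Generator, n: int, burstiness: float) -> np.ndarray:
    """Tokens per present word: 1 + geometric extras with mean ``burstiness``."""
    if burstiness == 0 or n == 0:
        return np.ones(n, dtype=np.int64)
    return rng.geometric(1.0 / (1.0 + burstiness), size=n)


def generate_corpus(spec: SyntheticCorpusSpec) -> list[Document]:
    """Generate ``n_spam + n_ham`` labeled documents, spam first.

    Each document samples which of its class's candidate words are present
    (exclusive words with probability ``discriminative_strength``, shared
    words with the tuned background probability), then repeats each present
    word a bursty number of times and shuffles the token order.  The same
    spec (including its seed) always yields an identical corpus.
    """
    rng = np.random.default_rng(spec.seed)
    docs: list[Document] = []
    plans = [("spam", spec.n_spam, spec.spam_words), ("ham", spec.n_ham, spec.ham_words)]
    p_shared = spec.shared_presence_prob
    for label, count, exclusive in plans:
        for i in range(count):
            present: list[str] = [
                w for w in exclusive if rng.random() < spec.discriminative_strength
            ]
            present += [w for w in spec.shared_words if rng.random() < p_shared]
            reps = _repeat_counts(rng, len(present), spec.burstiness)
            tokens: list[str] = []
            for w, r in zip(present, reps):
                tokens.extend([w] * int(r))
            rng.shuffle(tokens)
            docs.append(Document(tokens=tokens, label=label, source_id=f"{label}_{i:05d}"))
    return docs
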