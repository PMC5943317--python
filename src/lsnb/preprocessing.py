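"""Text cleaning and binary word-feature extraction.

Messages are reduced to lowercase alphabetic tokens (punctuation and
numerals act as separators, stop words and single characters are dropped),
a vocabulary keeps only words seen at least ``min_total_count`` times in
the corpus, and each document is encoded as the set of vocabulary words it
contains.
"""

from __future__ import annotations

import logging
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from .stopwords import ENGLISH_STOPWORDS

logger = logging.getLogger(__name__)

__all__ = [
    "CleaningConfig",
    "Document",
    "Vocabulary",
    "tokenize",
    "build_vocabulary",
    "vectorize",
]

_ALPHA_RUN = re.compile(r"[a-z]+")


@dataclass(frozen=True)
class CleaningConfig:
    """How raw message text becomes tokens.

    With ``alpha_only`` (the default) the text is lowercased and split on
    every non-alphabetic character, so numerals and punctuation can never
    survive inside a token.  ``raw()`` gives a whitespace-splitting,
    filter-free configuration for corpora whose files already contain clean
    tokens (e.g. generated synthetic corpora).
    """

    alpha_only: bool = True
    min_token_len: int = 2
    stopwords: frozenset[str] = ENGLISH_STOPWORDS
    strip_headers: bool = False

    @classmethod
    def raw(cls) -> "CleaningConfig":
        """Whitespace tokenization with no filtering (pre-tokenized input)."""
        return cls(alpha_only=False, min_token_len=1, stopwords=frozenset())


@dataclass
class Document:
    """A tokenized message with an optional class label."""

    tokens: list[str]
    label: Optional[str] = None
    source_id: str = ""


class Vocabulary:
    """Ordered, duplicate-free word set with stable index positions."""

    def __init__(self, words: Iterable[str]):
        ordered: list[str] = []
        seen: set[str] = set()
        for w in words:
            if w not in seen:
                seen.add(w)
                ordered.append(w)
        self._words: tuple[str, ...] = tuple(ordered)
        self._index: dict[str, int] = {w: i for i, w in enumerate(self._words)}

    @property
    def words(self) -> tuple[str, ...]:
        return self._words

    def index(self, word: str) -> int:
        return self._index[word]

    def __contains__(self, word: object) -> bool:
        return word in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self._words)

    def __len__(self) -> int:
        return len(self._words)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Vocabulary) and self._words == other._words

    def __repr__(self) -> str:
        return f"Vocabulary({len(self)} words)"


def tokenize(text: str, config: CleaningConfig = CleaningConfig()) -> list[str]:
    """Clean one message into a token list.

    Lowercases, splits on non-alphabetic characters (so punctuation and
    digit-bearing strings are discarded), then removes stop words and tokens
    shorter than ``min_token_len``.
    """
    if config.strip_headers:
        head, sep, body = text.partition("\n\n")
        if sep:
            text = body
    text = text.lower()
    if config.alpha_only:
        tokens = _ALPHA_RUN.findall(text)
    else:
        tokens = text.split()
    return [
        t
        for t in tokens
        if len(t) >= config.min_token_len and t not in config.stopwords
    ]


def build_vocabulary(
    documents: Sequence[Document],
    min_total_count: int = 2,
    stopwords: frozenset[str] = ENGLISH_STOPWORDS,
) -> Vocabulary:
    """Collect words whose total token count over ``documents`` reaches
    ``min_total_count``, in lexicographic order.

    Content words recur within documents (burstiness), so words seen only
    once in the whole corpus are unlikely to be informative features;
    ``min_total_count=2`` drops them.  Set ``min_total_count=1`` to disable
    the filter.
    """
    if min_total_count < 1:
        raise ValueError("min_total_count must be >= 1")
    if not documents:
        warnings.warn("building vocabulary from an empty document list", stacklevel=2)
        return Vocabulary([])
    counts: Counter[str] = Counter()
    for doc in documents:
        counts.update(doc.tokens)
    kept = sorted(
        w for w, n in counts.items() if n >= min_total_count and w not in stopwords
    )
    if not kept:
        warnings.warn(
            f"no word occurs at least {min_total_count} times; vocabulary is empty",
            stacklevel=2,
        )
    logger.info(
        "vocabulary: %d/%d words kept (min_total_count=%d)",
        len(kept), len(counts), min_total_count,
    )
    return Vocabulary(kept)


def vectorize(tokens: Iterable[str], vocab: Vocabulary) -> frozenset[str]:
    """Binary presence encoding: the vocabulary words occurring in ``tokens``."""
    return frozenset(t for t in set(tokens) if t in vocab)
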