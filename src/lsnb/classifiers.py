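"""Naive Bayes and its loosely symmetric variants.

Three classifier variants share one fitted parameterization:

* ``nb`` — Bernoulli naive Bayes; a word's weight in class ``c`` is the
  (optionally add-one smoothed) document frequency ``P(w|c)``.
* ``lsnb`` — each word/class pair is mapped onto a 2x2 table
  ``(P(w|c), P(~w|c), P(w|~c), P(~w|~c))`` and weighted by the LS strength,
  injecting symmetric and mutually exclusive bias into the likelihood.
* ``elsnb`` — the LSNB table cells are additionally scaled by word
  densities ``WD(c,w)`` (the share of class ``c``'s tokens contributed by
  ``w``), with the cross-pairing ``a·WD(c,w), b·WD(~c,w), c·WD(~c,w),
  d·WD(c,w)``.

Scores are accumulated in log space over the words *present* in a document;
absence factors are not multiplied in.  Exact ties are resolved to ``ham``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .ls_core import ContingencyTable, Direction, DomainError, ls_strength
from .preprocessing import Document, Vocabulary, build_vocabulary, vectorize

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANTS",
    "CLASSES",
    "ClassConditionals",
    "ClassifierModel",
    "PredictionResult",
    "fit",
    "word_table",
    "word_weight",
    "predict",
    "save_model",
    "load_model",
]

VARIANTS = ("nb", "lsnb", "elsnb")
CLASSES = ("spam", "ham")

TIE_TOL = 1e-9


@dataclass
class ClassConditionals:
    """Per-class word statistics estimated from a training set.

    ``doc_freq[c][w]`` counts training documents of class ``c`` containing
    ``w`` at least once; ``token_count[c][w]`` counts total occurrences.
    ``prob_present`` derives P(w|c) from document frequencies (add-one
    smoothed when requested) so that P(w|c) + P(~w|c) = 1, and ``density``
    derives WD(c,w) = N(c,w) / sum_k N(c,w_k) from token counts.
    """

    doc_counts: dict[str, int]
    doc_freq: dict[str, dict[str, int]]
    token_count: dict[str, dict[str, int]]
    smoothing: bool = False

    def prob_present(self, word: str, label: str) -> float:
        n = self.doc_counts[label]
        df = self.doc_freq[label].get(word, 0)
        if self.smoothing:
            return (df + 1) / (n + 2)
        return df / n if n else 0.0

    def density(self, word: str, label: str) -> float:
        total = sum(self.token_count[label].values())
        if total == 0:
            return 0.0
        return self.token_count[label].get(word, 0) / total


@dataclass
class ClassifierModel:
    """A fitted classifier: variant tag, priors, conditionals, vocabulary."""

    variant: str
    priors: dict[str, float]
    conditionals: ClassConditionals
    vocabulary: Vocabulary
    log_floor: float = 1e-12
    no_bias: bool = False  # debug: force LS correction terms to zero

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if not math.isclose(sum(self.priors.values()), 1.0, rel_tol=1e-9):
            raise ValueError(f"priors must sum to 1, got {self.priors}")

    # convenience wrappers
    def word_table(self, word: str, label: str) -> ContingencyTable:
        return word_table(self, word, label)

    def word_weight(self, word: str, label: str) -> float:
        return word_weight(self, word, label)

    def predict(self, features: Iterable[str]) -> "PredictionResult":
        return predict(self, features)


@dataclass(frozen=True)
class PredictionResult:
    log_scores: dict[str, float]
    label: str
    tie: bool


def _other(label: str) -> str:
    if label not in CLASSES:
        raise ValueError(f"unknown class {label!r}")
    return CLASSES[1] if label == CLASSES[0] else CLASSES[0]


def fit(
    train: Sequence[Document],
    variant: str = "lsnb",
    *,
    vocabulary: Optional[Vocabulary] = None,
    min_total_count: int = 2,
    priors: Optional[dict[str, float]] = None,
    smoothing: Optional[bool] = None,
    log_floor: float = 1e-12,
    no_bias: bool = False,
) -> ClassifierModel:
    """Estimate a model from labeled training documents.

    ``P(w|c)`` is the fraction of class-``c`` documents containing ``w``
    (Bernoulli presence, so ``a + b = 1`` per word); ``N(c,w)`` is the raw
    token count feeding the word densities.  Priors default to the equal
    0.5/0.5 used to avoid any initial class asymmetry.  ``smoothing``
    defaults per variant: add-one for ``nb`` (whose raw zero estimates
    annihilate the product), none for the LS variants (their correction
    terms already damp zeros).

    Raises
    ------
    ValueError
        If a class has no training documents, if labels are not exactly
        spam/ham, or the variant is unknown.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    labels = {doc.label for doc in train}
    if not labels <= set(CLASSES):
        raise ValueError(
            f"only binary spam/ham classification is supported; got labels {sorted(map(str, labels))}"
        )
    for cls in CLASSES:
        if not any(doc.label == cls for doc in train):
            raise ValueError(f"cannot fit: class {cls!r} has no training documents")

    if vocabulary is None:
        vocabulary = build_vocabulary(train, min_total_count=min_total_count)
    if priors is None:
        priors = {"spam": 0.5, "ham": 0.5}
    if smoothing is None:
        smoothing = variant == "nb"

    doc_counts = {c: 0 for c in CLASSES}
    doc_freq: dict[str, dict[str, int]] = {c: {} for c in CLASSES}
    token_count: dict[str, dict[str, int]] = {c: {} for c in CLASSES}
    for doc in train:
        c = doc.label
        doc_counts[c] += 1
        present = set()
        for tok in doc.tokens:
            if tok in vocabulary:
                present.add(tok)
                token_count[c][tok] = token_count[c].get(tok, 0) + 1
        for w in present:
            doc_freq[c][w] = doc_freq[c].get(w, 0) + 1

    conds = ClassConditionals(doc_counts, doc_freq, token_count, smoothing=smoothing)
    logger.info(
        "fit %s: %d spam / %d ham docs, |vocab|=%d, smoothing=%s",
        variant, doc_counts["spam"], doc_counts["ham"], len(vocabulary), smoothing,
    )
    return ClassifierModel(
        variant=variant,
        priors=dict(priors),
        conditionals=conds,
        vocabulary=vocabulary,
        log_floor=log_floor,
        no_bias=no_bias,
    )


def word_table(model: ClassifierModel, word: str, label: str) -> ContingencyTable:
    """The 2x2 table for one word/class pair under the model's variant.

    ``lsnb``:  (a,b,c,d) = (P(w|c), P(~w|c), P(w|~c), P(~w|~c)).
    ``elsnb``: the same cells scaled by word densities with the printed
    cross-pairing — a and d carry WD(c,w), b and c carry WD(~c,w).

    Raises
    ------
    KeyError
        If ``word`` is not in the model vocabulary.
    """
    if word not in model.vocabulary:
        raise KeyError(f"word {word!r} not in vocabulary")
    other = _other(label)
    conds = model.conditionals
    p_c = conds.prob_present(word, label)
    p_o = conds.prob_present(word, other)
    a, b = p_c, 1.0 - p_c
    c, d = p_o, 1.0 - p_o
    if model.variant == "elsnb":
        wd_c = conds.density(word, label)
        wd_o = conds.density(word, other)
        a, b, c, d = a * wd_c, b * wd_o, c * wd_o, d * wd_c
    return ContingencyTable(a, b, c, d)


def word_weight(model: ClassifierModel, word: str, label: str) -> float:
    """Per-word likelihood factor for ``label``.

    LS variants evaluate the LS strength of :func:`word_table`; ``nb`` uses
    the plain conditional probability ``a/(a+b) = P(w|c)``.  A degenerate
    all-zero table (possible for ``elsnb`` when both densities vanish)
    yields weight 0 with a warning.
    """
    if word not in model.vocabulary:
        raise KeyError(f"word {word!r} not in vocabulary")
    if model.variant == "nb":
        return model.conditionals.prob_present(word, label)
    try:
        table = word_table(model, word, label)
    except Exception as exc:  # all-zero table rejected by ContingencyTable
        warnings.warn(
            f"degenerate table for word {word!r}, class {label!r}: {exc}; weight set to 0",
            stacklevel=2,
        )
        return 0.0
    if model.no_bias:
        denom = table.a + table.b
        return table.a / denom if denom else 0.0
    try:
        return ls_strength(table, Direction.Q_GIVEN_P)
    except DomainError as exc:
        warnings.warn(
            f"degenerate table for word {word!r}, class {label!r}: {exc}; weight set to 0",
            stacklevel=2,
        )
        return 0.0


def predict(model: ClassifierModel, features: Iterable[str]) -> PredictionResult:
    """Score both classes on a feature set and return the argmax label.

    log-score(c) = log P(c) + sum over present vocabulary words of
    log max(weight(w,c), log_floor).  Out-of-vocabulary features are
    ignored; an empty feature set falls back to the priors, which ties and
    therefore predicts ``ham``.
    """
    present = vectorize(features, model.vocabulary)
    scores: dict[str, float] = {}
    for cls in CLASSES:
        s = math.log(model.priors[cls]) if model.priors[cls] > 0 else math.log(model.log_floor)
        for w in sorted(present):
            s += math.log(max(word_weight(model, w, cls), model.log_floor))
        scores[cls] = s
    tie = abs(scores["spam"] - scores["ham"]) <= TIE_TOL
    label = "ham" if tie or scores["ham"] > scores["spam"] else "spam"
    return PredictionResult(log_scores=scores, label=label, tie=tie)


# ---------------------------------------------------------------------------
# plain-text model serialization


def save_model(model: ClassifierModel, path: str | Path) -> None:
    """Write the model as line-oriented key-value text.

    Counts are stored as integers and priors/options as reprs, so a
    save/load round trip reproduces the model exactly.
    """
    conds = model.conditionals
    lines = [
        f"variant\t{model.variant}",
        f"prior_spam\t{model.priors['spam']!r}",
        f"prior_ham\t{model.priors['ham']!r}",
        f"smoothing\t{int(conds.smoothing)}",
        f"log_floor\t{model.log_floor!r}",
        f"no_bias\t{int(model.no_bias)}",
        f"docs_spam\t{conds.doc_counts['spam']}",
        f"docs_ham\t{conds.doc_counts['ham']}",
        f"vocab_size\t{len(model.vocabulary)}",
    ]
    for w in model.vocabulary:
        df_s = conds.doc_freq["spam"].get(w, 0)
        df_h = conds.doc_freq["ham"].get(w, 0)
        n_s = conds.token_count["spam"].get(w, 0)
        n_h = conds.token_count["ham"].get(w, 0)
        lines.append(f"word\t{w}\t{df_s}\t{df_h}\t{n_s}\t{n_h}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_model(path: str | Path) -> ClassifierModel:
    """Inverse of :func:`save_model`."""
    header: dict[str, str] = {}
    words: list[str] = []
    doc_freq: dict[str, dict[str, int]] = {"spam": {}, "ham": {}}
    token_count: dict[str, dict[str, int]] = {"spam": {}, "ham": {}}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if parts[0] == "word":
            w, df_s, df_h, n_s, n_h = parts[1], *map(int, parts[2:6])
            words.append(w)
            if df_s:
                doc_freq["spam"][w] = df_s
            if df_h:
                doc_freq["ham"][w] = df_h
            if n_s:
                token_count["spam"][w] = n_s
            if n_h:
                token_count["ham"][w] = n_h
        else:
            header[parts[0]] = parts[1]
    conds = ClassConditionals(
        doc_counts={"spam": int(header["docs_spam"]), "ham": int(header["docs_ham"])},
        doc_freq=doc_freq,
        token_count=token_count,
        smoothing=bool(int(header["smoothing"])),
    )
    return ClassifierModel(
        variant=header["variant"],
        priors={"spam": float(header["prior_spam"]), "ham": float(header["prior_ham"])},
        conditionals=conds,
        vocabulary=Vocabulary(words),
        log_floor=float(header["log_floor"]),
        no_bias=bool(int(header.get("no_bias", "0"))),
    )
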