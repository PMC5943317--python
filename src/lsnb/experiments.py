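"""Biased-sampling training schedules, train/test protocol, and metrics.

Five schedules vary the spam/ham mix of the training draw:

* ``1-1`` — (40t, 40t) for t = 1..6 (50% spam)
* ``1-2`` — (24t, 40t) for t = 1..10 (37.5% spam)
* ``1-3`` — (8t, 40t) for t = 1..30 (~17% spam)
* ``2-1`` — (fixed, 40t) for t = 1..6, fixed in {25, 100}
* ``2-2`` — (40t, fixed) for t = 1..6, fixed in {25, 100}

Each replicate holds out a stratified random half of the corpus as test
data, draws the scheduled training sizes without replacement from the
remaining half, fits every requested variant, and scores spam accuracy
(recall on spam), ham accuracy (recall on ham) and the F-measure (F1 with
spam as the positive class).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import classifiers
from .preprocessing import Document, Vocabulary, build_vocabulary, vectorize

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentSchedule",
    "MetricsRecord",
    "make_schedule",
    "spam_share_percent",
    "evaluate",
    "run_experiment",
    "aggregate",
    "presence_matrix",
]

EXPERIMENT_IDS = ("1-1", "1-2", "1-3", "2-1", "2-2")
FIXED_SIZES = (25, 100)

RESULT_COLUMNS = [
    "experiment_id", "step_t", "n_spam", "n_ham",
    "variant", "replicate", "spam_acc", "ham_acc", "f_measure",
]


@dataclass(frozen=True)
class ExperimentSchedule:
    """Ordered (n_spam, n_ham) training sizes of one experiment."""

    experiment_id: str
    steps: tuple[tuple[int, int], ...]
    fixed_size: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.steps or any(min(s) < 1 for s in self.steps):
            raise ValueError("every step must request at least one document per class")

    def spam_shares(self) -> list[float]:
        """Per-step spam fraction of the training draw, as percentages."""
        return [100.0 * s / (s + h) for s, h in self.steps]


def make_schedule(experiment_id: str, fixed_size: Optional[int] = None) -> ExperimentSchedule:
    """Instantiate one of the five training schedules.

    ``fixed_size`` (25 or 100) is required for experiments 2-1 and 2-2 and
    rejected otherwise.
    """
    if experiment_id not in EXPERIMENT_IDS:
        raise ValueError(f"unknown experiment {experiment_id!r}; expected one of {EXPERIMENT_IDS}")
    if experiment_id in ("2-1", "2-2"):
        if fixed_size not in FIXED_SIZES:
            raise ValueError(f"experiment {experiment_id} requires fixed_size in {FIXED_SIZES}")
    elif fixed_size is not None:
        raise ValueError(f"experiment {experiment_id} takes no fixed_size")

    if experiment_id == "1-1":
        steps = tuple((40 * t, 40 * t) for t in range(1, 7))
    elif experiment_id == "1-2":
        steps = tuple((24 * t, 40 * t) for t in range(1, 11))
    elif experiment_id == "1-3":
        steps = tuple((8 * t, 40 * t) for t in range(1, 31))
    elif experiment_id == "2-1":
        steps = tuple((fixed_size, 40 * t) for t in range(1, 7))
    else:  # 2-2
        steps = tuple((40 * t, fixed_size) for t in range(1, 7))
    return ExperimentSchedule(experiment_id=experiment_id, steps=steps, fixed_size=fixed_size)


def spam_share_percent(n_spam: int, n_ham: int) -> float:
    """Spam fraction of a corpus or draw, as a percentage."""
    total = n_spam + n_ham
    if total <= 0:
        raise ValueError("empty corpus")
    return 100.0 * n_spam / total


@dataclass(frozen=True)
class MetricsRecord:
    """Confusion counts (spam positive) and the derived per-class metrics."""

    tp: int
    fp: int
    fn: int
    tn: int
    spam_acc: float
    ham_acc: float
    f_measure: float


def evaluate(predictions: Sequence[str], truth: Sequence[str]) -> MetricsRecord:
    """Confusion-matrix metrics with spam as the positive class.

    spam accuracy = TP/(TP+FN), ham accuracy = TN/(TN+FP), F-measure = F1.
    Zero-denominator precision/recall contribute an F of 0.
    """
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth differ in length")
    if not truth:
        raise ValueError("cannot evaluate an empty label sequence")
    if not {"spam", "ham"} <= set(truth):
        raise ValueError("truth must contain both classes")
    tp = sum(1 for p, t in zip(predictions, truth) if p == "spam" and t == "spam")
    fn = sum(1 for p, t in zip(predictions, truth) if p == "ham" and t == "spam")
    fp = sum(1 for p, t in zip(predictions, truth) if p == "spam" and t == "ham")
    tn = sum(1 for p, t in zip(predictions, truth) if p == "ham" and t == "ham")
    spam_acc = tp / (tp + fn)
    ham_acc = tn / (tn + fp)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = spam_acc
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MetricsRecord(tp=tp, fp=fp, fn=fn, tn=tn,
                         spam_acc=spam_acc, ham_acc=ham_acc, f_measure=f)


def presence_matrix(docs: Sequence[Document], vocab: Vocabulary) -> np.ndarray:
    """Binary docs x vocabulary matrix for external (sklearn-style) classifiers."""
    X = np.zeros((len(docs), len(vocab)), dtype=np.float64)
    for i, doc in enumerate(docs):
        for w in vectorize(doc.tokens, vocab):
            X[i, vocab.index(w)] = 1.0
    return X


def _split_half(
    indices: np.ndarray, labels: Sequence[str], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified half split: per class, a random half goes to test."""
    test_parts, pool_parts = [], []
    for cls in ("spam", "ham"):
        cls_idx = np.array([i for i in indices if labels[i] == cls])
        perm = rng.permutation(cls_idx)
        half = len(perm) // 2
        test_parts.append(perm[:half])
        pool_parts.append(perm[half:])
    return np.concatenate(test_parts), np.concatenate(pool_parts)


def _draw_training(
    pool: np.ndarray, labels: Sequence[str], n_spam: int, n_ham: int,
    rng: np.random.Generator,
) -> Optional[np.ndarray]:
    """Uniform stratified draw without replacement; None if the pool is short."""
    chosen = []
    for cls, need in (("spam", n_spam), ("ham", n_ham)):
        cls_pool = np.array([i for i in pool if labels[i] == cls])
        if len(cls_pool) < need:
            return None
        chosen.append(rng.choice(cls_pool, size=need, replace=False))
    return np.concatenate(chosen)


def run_experiment(
    corpus: Sequence[Document],
    schedule: ExperimentSchedule,
    variants: Sequence[str] = ("nb", "lsnb", "elsnb"),
    replicates: int = 10,
    seed: int = 0,
    *,
    vocabulary: Optional[Vocabulary] = None,
    min_total_count: int = 2,
    vocab_scope: str = "corpus",
    extra_classifiers: Optional[dict[str, Callable[[], object]]] = None,
    fit_options: Optional[dict] = None,
) -> pd.DataFrame:
    """Run a schedule and return one row per (step, variant, replicate).

    For each replicate a stratified random half of ``corpus`` is held out
    as the test set and training draws come from the other half, so train
    and test are always disjoint.  The vocabulary is built once over the
    whole corpus by default (``vocab_scope="corpus"``); pass
    ``vocab_scope="train"`` to rebuild it from each training draw instead
    and avoid any corpus-level leakage.

    ``extra_classifiers`` maps a name to a zero-argument factory returning
    an object with sklearn-style ``fit(X, y)`` / ``predict(X)`` on a binary
    presence matrix (y is 1 for spam); these baselines ride along in the
    result table next to the core variants.

    Steps the training pool cannot satisfy are skipped with a warning.
    The result is a deterministic function of (corpus, schedule, variants,
    replicates, seed).
    """
    for v in variants:
        if v not in classifiers.VARIANTS:
            raise ValueError(f"unknown variant {v!r}")
    if vocab_scope not in ("corpus", "train"):
        raise ValueError("vocab_scope must be 'corpus' or 'train'")
    labels = [doc.label for doc in corpus]
    if vocabulary is None and vocab_scope == "corpus":
        vocabulary = build_vocabulary(corpus, min_total_count=min_total_count)
    extra_classifiers = extra_classifiers or {}
    fit_options = fit_options or {}

    needed_spam = max(s for s, _ in schedule.steps)
    needed_ham = max(h for _, h in schedule.steps)
    logger.info(
        "experiment %s: corpus %d spam / %d ham, max draw (%d, %d), %d replicates",
        schedule.experiment_id, labels.count("spam"), labels.count("ham"),
        needed_spam, needed_ham, replicates,
    )

    rows = []
    child_seeds = np.random.SeedSequence(seed).spawn(replicates)
    all_idx = np.arange(len(corpus))
    for rep, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        test_idx, pool_idx = _split_half(all_idx, labels, rng)
        test_docs = [corpus[i] for i in test_idx]
        truth = [labels[i] for i in test_idx]
        for t, (n_spam, n_ham) in enumerate(schedule.steps, start=1):
            train_idx = _draw_training(pool_idx, labels, n_spam, n_ham, rng)
            if train_idx is None:
                warnings.warn(
                    f"step t={t} of {schedule.experiment_id} needs ({n_spam}, {n_ham}) "
                    "training documents but the pool is too small; skipped",
                    stacklevel=2,
                )
                continue
            train_docs = [corpus[i] for i in train_idx]
            if vocab_scope == "train":
                vocab = build_vocabulary(train_docs, min_total_count=min_total_count)
            else:
                vocab = vocabulary
            for variant in variants:
                model = classifiers.fit(train_docs, variant, vocabulary=vocab, **fit_options)
                preds = [model.predict(doc.tokens).label for doc in test_docs]
                m = evaluate(preds, truth)
                rows.append((schedule.experiment_id, t, n_spam, n_ham, variant, rep,
                             m.spam_acc, m.ham_acc, m.f_measure))
            if extra_classifiers:
                X_train = presence_matrix(train_docs, vocab)
                y_train = np.array([1 if corpus[i].label == "spam" else 0 for i in train_idx])
                X_test = presence_matrix(test_docs, vocab)
                for name, factory in extra_classifiers.items():
                    clf = factory()
                    clf.fit(X_train, y_train)
                    preds = ["spam" if y else "ham" for y in clf.predict(X_test)]
                    m = evaluate(preds, truth)
                    rows.append((schedule.experiment_id, t, n_spam, n_ham, name, rep,
                                 m.spam_acc, m.ham_acc, m.f_measure))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def aggregate(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of each metric over replicates.

    The standard error is the sample standard deviation (ddof=1) divided by
    the square root of the replicate count — the quantity drawn as error
    bars on the accuracy/F curves.
    """
    metrics = ["spam_acc", "ham_acc", "f_measure"]
    grouped = results.groupby(
        ["experiment_id", "step_t", "n_spam", "n_ham", "variant"], sort=True
    )[metrics]
    mean = grouped.mean().add_suffix("_mean")
    n = grouped.size()
    se = grouped.std(ddof=1).div(np.sqrt(n), axis=0).fillna(0.0).add_suffix("_se")
    out = pd.concat([mean, se, n.rename("replicates")], axis=1).reset_index()
    return out


def plot_results(agg: pd.DataFrame, out_path: str, metric: str = "f_measure") -> None:
    """Optional curve plot (mean ± SE per variant over steps); needs matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for variant, sub in agg.groupby("variant"):
        sub = sub.sort_values("step_t")
        ax.errorbar(sub["step_t"], sub[f"{metric}_mean"], yerr=sub[f"{metric}_se"],
                    marker="o", capsize=3, label=variant)
    ax.set_xlabel("step t")
    ax.set_ylabel(metric)
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
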