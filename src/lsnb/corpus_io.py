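"""Reading spam-corpus directory layouts and writing result artifacts.

Three layouts are understood:

* ``class_subdirs`` — one subdirectory per class (``spam/``, ``ham/``),
  one plain-text message per file.  This is also the layout the synthetic
  generator writes.
* ``lingspam_parts`` — ``part1..partN`` folders whose files are labeled by
  the ``spmsg`` filename prefix (spam) or its absence (ham).
* ``filename_prefix`` — a flat or nested tree where any filename starting
  with a configurable prefix is spam.

Files are decoded as UTF-8 with a Latin-1 fallback (legacy email corpora
are dirty); hidden files and non-text extensions are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .preprocessing import CleaningConfig, Document, tokenize
from .experiments import RESULT_COLUMNS

logger = logging.getLogger(__name__)

__all__ = ["CorpusLayout", "load_corpus", "write_corpus", "write_results", "read_results"]

STYLES = ("class_subdirs", "lingspam_parts", "filename_prefix")
_TEXT_SUFFIXES = {"", ".txt", ".text", ".msg", ".eml"}


@dataclass(frozen=True)
class CorpusLayout:
    """Where a corpus lives and how files map to labels."""

    root: Path
    style: str = "class_subdirs"
    spam_prefix: str = "spmsg"

    def __post_init__(self) -> None:
        if self.style not in STYLES:
            raise ValueError(f"unknown corpus style {self.style!r}; expected one of {STYLES}")


def _read_text(path: Path) -> str:
    data = path.read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        logger.info("non-UTF-8 file %s decoded as Latin-1", path)
        return data.decode("latin-1", errors="replace")


def _iter_files(root: Path):
    for path in sorted(root.rglob("*")):
        if path.is_file() and not path.name.startswith(".") and path.suffix.lower() in _TEXT_SUFFIXES:
            yield path


def load_corpus(
    layout: CorpusLayout | str | Path,
    config: CleaningConfig = CleaningConfig(),
) -> list[Document]:
    """Load and tokenize every message under the layout's root.

    Returns documents in deterministic (sorted-path) order.  Unreadable
    files are skipped with a warning; a class with zero messages is an
    error.
    """
    if not isinstance(layout, CorpusLayout):
        layout = CorpusLayout(root=Path(layout))
    root = Path(layout.root)
    if not root.is_dir():
        raise FileNotFoundError(f"corpus root {root} does not exist")

    docs: list[Document] = []
    for path in _iter_files(root):
        rel = path.relative_to(root)
        if layout.style == "class_subdirs":
            if not rel.parts[:-1] or rel.parts[0] not in ("spam", "ham"):
                continue
            label = rel.parts[0]
        elif layout.style == "lingspam_parts":
            if not (rel.parts[:-1] and rel.parts[0].startswith("part")):
                continue
            label = "spam" if path.name.startswith("spmsg") else "ham"
        else:  # filename_prefix
            label = "spam" if path.name.startswith(layout.spam_prefix) else "ham"
        try:
            text = _read_text(path)
        except OSError as exc:
            logger.warning("skipping unreadable file %s: %s", path, exc)
            continue
        docs.append(Document(tokens=tokenize(text, config), label=label, source_id=str(rel)))

    n_spam = sum(1 for d in docs if d.label == "spam")
    n_ham = len(docs) - n_spam
    logger.info("loaded corpus %s (%s): %d spam / %d ham", root, layout.style, n_spam, n_ham)
    for cls, n in (("spam", n_spam), ("ham", n_ham)):
        if n == 0:
            raise ValueError(f"corpus {root} contains no {cls} messages")
    return docs


def write_corpus(docs: list[Document], out_dir: str | Path) -> None:
    """Write documents in the ``class_subdirs`` layout (one file per message,
    tokens space-separated) so generated corpora round-trip through
    :func:`load_corpus` with ``CleaningConfig.raw()``."""
    out = Path(out_dir)
    for cls in ("spam", "ham"):
        (out / cls).mkdir(parents=True, exist_ok=True)
    counters = {"spam": 0, "ham": 0}
    for doc in docs:
        if doc.label not in counters:
            raise ValueError(f"document {doc.source_id!r} has label {doc.label!r}")
        name = f"{doc.label}_{counters[doc.label]:05d}.txt"
        counters[doc.label] += 1
        (out / doc.label / name).write_text(" ".join(doc.tokens) + "\n", encoding="utf-8")
    logger.info("wrote %d spam / %d ham messages to %s", counters["spam"], counters["ham"], out)


def write_results(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV, sorted by (experiment, step, variant,
    replicate) for deterministic output."""
    if records.empty:
        raise ValueError("refusing to write an empty result table")
    missing = [c for c in RESULT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"result table is missing columns {missing}")
    ordered = records.sort_values(
        ["experiment_id", "step_t", "variant", "replicate"], kind="mergesort"
    )
    ordered.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_results`."""
    return pd.read_csv(path)
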