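"""Embedded English stop-word list.

A copy of the widely used 179-word English list (function words plus
contraction fragments) so that the package works offline.  A custom list can
be supplied instead via :func:`load_stopwords` or the ``--stopwords`` CLI
flag (one word per line, UTF-8, ``#`` comments ignored).
"""

from __future__ import annotations

from pathlib import Path

ENGLISH_STOPWORDS: frozenset[str] = frozenset("""
i me my myself we our ours ourselves you your yours yourself yourselves
he him his himself she her hers herself it its itself they them their
theirs themselves what which who whom this that these those am is are
was were be been being have has had having do does did doing a an the
and but if or because as until while of at by for with about against
between into through during before after above below to from up down in
out on off over under again further then once here there when where why
how all any both each few more most other some such no nor not only own
same so than too very s t can will just don should now d ll m o re ve y
ain aren couldn didn doesn hadn hasn haven isn ma mightn mustn needn
shan shouldn wasn weren won wouldn
""".split())


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stop-word file: one lowercase word per line, ``#`` comments allowed."""
    words = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        word = line.split("#", 1)[0].strip().lower()
        if word:
            words.append(word)
    return frozenset(words)
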