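"""Independent reference implementations used only by the test suite.

Everything here is a deliberately literal, slow transcription of the model
formulas, written separately from the library code: plain nested loops and
dictionaries, no shared helpers with ``lsnb``.  The tests compare library
output against these functions on random inputs.
"""

from __future__ import annotations

import math


def _frac(num, den):
    return 0.0 if den == 0 else num / den


# --- the four LS directions, transcribed term by term -----------------------

def ls_q_given_p(a, b, c, d):
    return (a + _frac(b * d, b + d)) / (
        a + b + _frac(a * c, a + c) + _frac(b * d, b + d)
    )


def ls_notq_given_p(a, b, c, d):
    return (b + _frac(a * c, a + c)) / (
        a + b + _frac(a * c, a + c) + _frac(b * d, b + d)
    )


def ls_p_given_q(a, b, c, d):
    return (a + _frac(c * d, c + d)) / (
        a + c + _frac(a * b, a + b) + _frac(c * d, c + d)
    )


def ls_notq_given_notp(a, b, c, d):
    return (d + _frac(a * c, a + c)) / (
        c + d + _frac(a * c, a + c) + _frac(b * d, b + d)
    )


# --- brute-force classifier scoring from raw documents ----------------------

def count_stats(train_docs, vocab_words):
    """Document frequencies, token counts and per-class document totals,
    recomputed with plain loops."""
    n_docs = {"spam": 0, "ham": 0}
    df = {"spam": {w: 0 for w in vocab_words}, "ham": {w: 0 for w in vocab_words}}
    tc = {"spam": {w: 0 for w in vocab_words}, "ham": {w: 0 for w in vocab_words}}
    for doc in train_docs:
        n_docs[doc.label] += 1
        for w in vocab_words:
            occurrences = sum(1 for t in doc.tokens if t == w)
            if occurrences > 0:
                df[doc.label][w] += 1
                tc[doc.label][w] += occurrences
    return n_docs, df, tc


def prob_present(df, n_docs, word, label, smoothing):
    if smoothing:
        return (df[label][word] + 1) / (n_docs[label] + 2)
    return df[label][word] / n_docs[label]


def word_density(tc, word, label):
    total = sum(tc[label].values())
    return 0.0 if total == 0 else tc[label][word] / total


def table_for(df, n_docs, tc, word, label, variant, smoothing):
    other = "ham" if label == "spam" else "spam"
    p = prob_present(df, n_docs, word, label, smoothing)
    q = prob_present(df, n_docs, word, other, smoothing)
    a, b, c, d = p, 1 - p, q, 1 - q
    if variant == "elsnb":
        wd_own = word_density(tc, word, label)
        wd_other = word_density(tc, word, other)
        a = a * wd_own
        b = b * wd_other
        c = c * wd_other
        d = d * wd_own
    return a, b, c, d


def score_document(train_docs, vocab_words, doc_tokens, variant,
                   priors=(0.5, 0.5), smoothing=None, floor=1e-12):
    """Log-scores {spam, ham} for one document, rebuilt from raw counts."""
    if smoothing is None:
        smoothing = variant == "nb"
    n_docs, df, tc = count_stats(train_docs, vocab_words)
    present = sorted(set(t for t in doc_tokens if t in set(vocab_words)))
    scores = {}
    for label, prior in zip(("spam", "ham"), priors):
        s = math.log(prior)
        for w in present:
            if variant == "nb":
                weight = prob_present(df, n_docs, w, label, smoothing)
            else:
                a, b, c, d = table_for(df, n_docs, tc, w, label, variant, smoothing)
                if a + b + _frac(a * c, a + c) + _frac(b * d, b + d) == 0:
                    weight = 0.0
                else:
                    weight = ls_q_given_p(a, b, c, d)
            s += math.log(max(weight, floor))
        scores[label] = s
    return scores
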