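# lsnb

Loosely symmetric naive Bayes text classification.

The loosely symmetric (LS) model scores the association between two binary
events from their 2×2 contingency table. It is a conditional probability
modified by two correction terms, `ac/(a+c)` and `bd/(b+d)`, that
interpolate between no bias and complete symmetric ("if q then p" from
"if p then q") and mutually exclusive ("if not-p then not-q") bias —
tendencies observed in human inference. This package implements:

- **`lsnb.ls_core`** — the LS model on 2×2 tables (all four directional
  strengths) plus the classical comparators (conditional probability,
  ΔP, the dual-factor heuristic).
- **`lsnb.preprocessing`** — message cleaning (lowercase alphabetic tokens,
  stop-word and singleton filtering), vocabulary construction, binary
  presence feature vectors.
- **`lsnb.classifiers`** — three Bernoulli spam/ham classifiers sharing one
  fitted parameterization: plain naive Bayes (`nb`), LS-weighted naive
  Bayes (`lsnb`, each word's likelihood factor is the LS strength of its
  per-class presence table), and the word-density-enhanced variant
  (`elsnb`, table cells scaled by each class's token-share of the word).
  Models serialize to plain text and round-trip exactly.
- **`lsnb.experiments`** — the biased-sampling training schedules
  (balanced, 38%-spam, 17%-spam, and fixed-class-size geometries), a
  stratified half-split train/test protocol with seeded replicates, and
  per-class accuracy / F-measure metrics with standard errors. External
  sklearn-style classifiers can ride along as baselines.
- **`lsnb.synthetic`** — a seeded generator for two-class corpora with
  shared and class-exclusive vocabulary and bursty token repetition, so
  the whole pipeline runs with no downloads.
- **`lsnb.corpus_io`** — loaders for standard spam-corpus directory
  layouts (class subdirectories, Ling-Spam style `partN` folders with the
  `spmsg` filename prefix, generic filename-prefix trees) and CSV result
  output.

## CLI

```sh
# LS strength of a table, printed to 6 decimals
lsnb ls-eval 2 1 1 3                      # -> 0.622642
lsnb ls-eval 2 1 1 2 --direction notq_given_notp

# end-to-end on a generated corpus
lsnb generate --out corpus --n-spam 100 --n-ham 400 --strength 0.6 --seed 7
lsnb train --variant elsnb --corpus corpus --raw --out model.txt
lsnb predict --model model.txt --input corpus/spam/spam_00000.txt --raw
lsnb experiment --id 2-1 --fixed-size 25 --corpus corpus --raw \
    --variants nb,lsnb,elsnb --replicates 10 --seed 42 --out results.csv
```

Real corpora are read with `--style class_subdirs` (spam/ham folders) or
`--style lingspam_parts`; `--strip-headers` skips everything before the
first blank line of raw email files, `--stopwords FILE` replaces the
embedded stop-word list, and `--config FILE` supplies flat `key=value`
defaults (`train.variant=elsnb`).

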