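# Methods

This note records the model, the estimation conventions, the defaults and
the deliberately made design choices behind `causepattern`, at the level of
detail a maintainer or reviewer needs to reason about results.

## Units of analysis and preprocessing

The unit is a *sentence pair*: a cause span and an effect span of
pre-tokenized, POS-tagged tokens, labeled causality / non-causality.
Explicit causality sentences are turned into pairs by removing the
discourse connective; the connective lexicon carries, per connective, which
side of it holds the cause (`because` → cause after, `so` → cause before).
Sentences with several connective occurrences are split on the first
(a warning is logged); splits that would leave an empty span are skipped.
The package is language-agnostic by design: tokenization, segmentation and
tagging are upstream concerns, and POS tags are collapsed to
noun/verb/other because only nouns and verbs participate in pattern
generation. Word identity is case-folded for mining and feature matching.

## Pattern mining

**Transaction model.** Support of a word set is the number of *spans*
containing every word (repeats within one span count once); support of a
pattern set is the number of *pairs* containing every pattern on its own
side. This is the classical Apriori transaction model, extended so that at
the second stage the items are themselves patterns.

**Apriori.** L₁ holds words with support ≥ min_support; C_k is built from
L_{k−1} by merging sets that agree on their first k−2 items under a
canonical lexicographic order, candidates with any infrequent (k−1)-subset
are pruned, and a support count gives L_k; iteration stops at an empty
level or at `max_k`. Candidate counting picks per level between
candidate-driven subset checks and transaction-driven k-combination
enumeration, whichever is cheaper. Correctness is guarded by an
independent brute-force subset-enumeration oracle in the test suite.

**Confidence.** A frequent set of k ≥ 2 items becomes a pattern when its
pointwise mutual information P·ln(P/∏Pᵢ) clears the stage's confidence
rule. Natural log is used throughout (any fixed base only rescales
thresholds). A zero joint count scores 0 by the limit convention. At the
inter stage the joint probability is over pairs and each marginal is the
pattern's containment frequency in its own side's spans; both denominators
equal the number of pairs, since each pair contributes one span per side.
Patterns store their words in first-occurrence order (so they print the
way they read) while mining uses the sorted canonical form; single words
are never patterns.

**Thresholds.** Each stage accepts either an absolute MI minimum or a
top-fraction rule (keep the best `ceil(fraction · count)` after sorting by
confidence with deterministic lexicographic tie-breaks). The pipeline
defaults are: `min_support = 2`; intra stage gated by an absolute minimum
of **0.01 nats**; inter stage gated by **top_fraction = 0.3**. The intra
default was set by inspecting the MI distribution on the default synthetic
benchmark: associations attributable to sampling noise concentrate well
below 0.01 (extreme order statistics reach ~0.06), while genuinely
dependent planted groups score ~0.2; the gate is also what keeps the inter
stage's candidate space tractable, since thousands of noise-level intra
patterns would otherwise enter pattern-set counting. `intra_max_k = 4`
bounds the word-set size; `inter_max_k = 2` means an inter pattern
combines one pattern per side, which is the form all known worked examples
take — larger combinations are supported via configuration but are
exponentially rarer and costlier.

**Parse-derived patterns.** As an alternative intra-pattern source, every
(dependent, head) arc of an externally produced dependency parse (CoNLL-U,
`# sent_id = <record-id>/<cause|effect>`) is a two-word pattern. Function
words are retained at extraction. Before entering the inter stage these
pairs pass the *same* support and MI-confidence filters as mined word
sets, so the two routes (`ISLP_ARM` vs `ISLP_parsing`) are comparable;
whether the original design filtered parse pairs at all is not
determinable, and applying equal filters is the comparability-preserving
choice. The CoNLL-U reader is a small internal implementation covering the
standard 10-column format, with validation of head ranges, single-rootedness
and acyclicity.

## Classifier

The detector is the factored model
c\* = argmax_c ∏ᵢ P(islpᵢ|c) ∏ P((wᵢ,wⱼ)|c) P(c), i.e. a naive-Bayes-style
product over two feature families: matched inter patterns and the cross
product of cause × effect content words. Features are sets — a feature
matched multiple times in one pair counts once. Estimation conventions:

* P(c) = N(c)/N with N counting sentence *pairs* (the classification
  unit), and P(f|c) = N(f,c)/N(c) with N(f,c) the number of class-c pairs
  exhibiting the feature.
* As written, an unseen feature annihilates the product, so the default is
  add-one smoothing against each family's training vocabulary:
  P(f|c) = (N(f,c)+1)/(N(c)+|V_family|), with unseen-at-test features
  receiving the same floor. `smoothing="none"` reproduces bare relative
  frequencies and ignores zero-count features. Note that with set-valued
  features a record may carry several features of one family, so the
  smoothed family table is a proper distribution over V only in the
  one-feature-per-record regime; the quantity that matters to the argmax
  is the per-feature likelihood ratio, which is well-defined regardless.
* All scoring is log-domain (the product underflows at realistic feature
  counts); an exact tie resolves to non-causality, the conservative
  default for a detector.

Models persist as versioned JSON holding raw counts, priors and the
smoothing mode, so both smoothing behaviours can be evaluated from one
file.

## Evaluation harness

Recall = TP/(TP+FN), Precision = TP/(TP+FP), F = 2RP/(R+P), with
causality as the positive class and the 0/0 conventions R = P = F = 0 (no
predicted positives ⇒ precision 0). Cross-validation is stratified (ids
shuffled per class with a seeded generator and dealt round-robin, the deal
position carried across classes so fold sizes balance) and re-mines
patterns inside every fold from that fold's training causality pairs only;
id-disjointness of train and test is asserted. Mining from the
causality-labeled pairs follows the framework's structure (patterns
characterize cause–effect structure; both classes then contribute to
probability estimation). Feature sets are compared by a paired two-tailed
t-test on per-fold F values; identical fold lists give t = 0, p = 1, and a
zero-variance nonzero difference is reported as significant with a
`degenerate` flag since the statistic is undefined. Sweeps vary either the
fraction of each fold's training split (learning curve) or the inter-stage
top fraction, reporting mean metrics per feature set.

## Synthetic benchmark

The target corpora (clinical/forum text with causality annotations) are
private, so all quantitative claims in this repository are made on
generated data whose structure mirrors what the method exploits:

* **Class balance** 2835/8035 ≈ 0.353 causality, the ratio of the
  reference corpus the method was designed around.
* **Planted intra structure**: six cause-side and six effect-side word
  groups of two words each, each group appearing as a unit in any span
  with base probability 0.05 per span in both classes — this is what makes
  groups frequent and high-MI within a side.
* **Planted inter structure**: group i on the cause side is linked to
  group i on the effect side. Per pair one link is chosen uniformly and
  *co-fires* (injects both its groups) with probability 0.6 in causality
  pairs vs 0.05 in non-causality pairs — cross-boundary dependence
  concentrated in the causality class.
* **Ambiguity**: every planted word also appears solo with probability
  0.05 per span, and spans are padded with 5–9 tokens drawn from a
  120-word background vocabulary (70 % tagged noun/verb, the rest filtered
  out by the POS gate). Solo appearances make individual word pairs fire
  spuriously in both classes, so WP features are informative but noisy,
  while a full pattern match (all group words on both sides) remains
  strongly class-associated. Words are abstract symbols (`cw3_a`,
  `ew5_b`, `bg017`); the method sees only co-occurrence, so no linguistic
  realism is attempted.

Defaults (2,000 pairs, the numbers above) constitute the
`default_benchmark`; a fixed seed yields a byte-identical corpus. What
passing on this benchmark shows: the miner recovers exactly the planted
dependence structure, and pattern features add detection power over word
pairs when cross-boundary dependence genuinely exists. What it does not
show: performance on real language, where pattern word order, synonymy,
topic drift and annotation noise all matter and none are modeled. The
ceiling is also intentionally below 1: a causality pair whose link did not
fire (probability 0.4) is statistically indistinguishable from a
non-causality pair, so recall around 0.6 is the best any detector can do
here.

## Numerical and degenerate-input conventions

* MI with zero joint support returns 0; marginals of support 0 are a
  caller error (every mined item has support ≥ 1 by construction).
* `select_top_patterns` and intra selection use `ceil(fraction · count)`
  and break confidence ties lexicographically on pattern words, so every
  selection is a deterministic prefix of the sorted list and monotone in
  the fraction.
* Empty corpora, empty spans after POS filtering, a side with no intra
  patterns, and min_support above the corpus size all degrade to empty
  results with a logged warning rather than an error.
* Training requires at least one pair of each class; unlabeled records are
  excluded from CV.

## Problem sizes

The bundled test and acceptance runs use: 200 random corpora (≤ 30 spans,
vocabulary 12) for the mining oracle, 100 random small models for the
classifier oracle, and the 2,000-pair benchmark with 10-fold CV for the
feature-set comparison — sizes at which every check runs in minutes on a
single core while leaving the measured effects far from their decision
thresholds.

## Known limitations

* The minimum-support/confidence defaults are corpus-scale-dependent; real
  corpora need the same development-set tuning the original protocol used.
* `ISLP_parsing` quality is bounded by the external parser; no parses are
  produced here.
* The classifier's independence assumptions double-count correlated
  features (a pattern and its constituent word pairs); this is inherent to
  the factored model, not an implementation artifact.
* Explicit-causality detection at test time (connective matching) is out
  of scope: connectives serve only to construct training pairs.
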