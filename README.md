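# causepattern

Detecting implicit cause–effect relations between sentences by mining
**inter-sentential language patterns**.

## The problem

Texts written by people describing their problems — for instance posts on
mental-health forums — are full of cause–effect relations between
sentences: *"I broke up with my boyfriend. Life is now meaningless to me."*
When a discourse connective ("because", "so") is present the relation is
explicit and easy to spot; when it is absent the relation is *implicit* and
must be inferred from the words alone. Earlier work used **word pairs**
(WP) — one word from the cause span crossed with one from the effect span,
e.g. *(broke up, life)*, *(boyfriend, meaningless)* — but individual words
rarely capture an event, so such features are semantically incomplete.

This package detects implicit causality with features that span the
sentence boundary as *combinations of word combinations*:

* an **intra-sentential language pattern** (lp) is a set of ≥ 2 words that
  frequently co-occur within the cause (or effect) spans, e.g.
  `<broke_up, boyfriend>`;
* an **inter-sentential language pattern** (islp) combines at least one
  cause-side and one effect-side intra pattern that frequently co-occur
  across the boundary, e.g. `<<broke_up, boyfriend>, <life, meaningless>>`.

## The method

**Mining.** Frequent word sets are found with an Apriori iteration over
spans as transactions (join step: merge frequent (k−1)-sets sharing their
first k−2 words; prune step: drop candidates with infrequent subsets, then
count support). Only nouns and verbs participate. A frequent set
`lp = <w₁,…,w_k>` becomes a pattern if its pointwise mutual information

```
Conf(lp) = MI(w₁,…,w_k) = P(w₁,…,w_k) · log( P(w₁,…,w_k) / ∏ᵢ P(wᵢ) )
```

clears a confidence threshold, with probabilities estimated as
span-containment frequencies. The same machinery is then re-run with
*patterns* as items and *sentence pairs* as transactions, scoring candidate
cross-boundary sets by the same MI over pair-containment probabilities;
scored inter patterns are ranked by confidence and the top *N* % kept.
Intra patterns can alternatively be derived from dependency parses: every
(dependent, head) arc is a two-word pattern (`ISLP_parsing` vs `ISLP_ARM`).

**Detection.** A sentence pair (sᵢ, sⱼ) is classified by the factored
probabilistic model

```
c* = argmax_c  ∏ᵢ P(islpᵢ | c) · ∏_{wᵢ∈sᵢ, wⱼ∈sⱼ} P((wᵢ,wⱼ) | c) · P(c)
```

over c ∈ {causality, non-causality}, with probabilities estimated as
relative frequencies over training pairs, add-one smoothing over each
feature family's vocabulary (configurable), and all arithmetic in the log
domain. Performance is measured by recall, precision and F-measure under
stratified k-fold cross-validation with per-fold re-mining (no test pair
ever influences pattern discovery), and feature sets are compared with a
paired two-tailed t-test over per-fold F values.

Because the corpora this method targets are typically private, the package
ships a synthetic-corpus generator that plants dependent word groups within
spans and class-dependent group co-activations across spans, with a gold
inventory for recovery checks (see `docs/methods.md`).

## Worked example

Mining the bundled six-pair mini-corpus and featurizing the example pair
above:

```python
from causepattern import load_corpus, mine_inventory, PipelineConfig, featurize

pairs = load_corpus("tests/data/worked_examples/fig1b_corpus.jsonl")
cfg = PipelineConfig(min_support=2, intra_min_confidence=0.0, top_fraction=1.0)
inventory = mine_inventory(pairs, cfg)
for pat in inventory:
    print(f"{pat}  support={pat.support}  confidence={pat.confidence:.4f}")

[e3] = load_corpus("tests/data/worked_examples/e3_pair.jsonl")
feats = featurize(e3, inventory)
print("word pairs:", sorted(feats.word_pairs))
```

prints

```
<<<failed, exam>>, <<felt, upset>>>  support=2  confidence=0.3662
<<<broke_up, boyfriend>>, <<life, meaningless>>>  support=3  confidence=0.3466
word pairs: [('boyfriend', 'life'), ('boyfriend', 'meaningless'), ('broke_up', 'life'), ('broke_up', 'meaningless')]
```

Two inter patterns are mined. `<broke_up, boyfriend>` and
`<life, meaningless>` each occur in 3 of the 6 pairs and always together,
so the joint probability 0.5 exceeds the marginal product 0.25 and the
confidence is 0.5·ln 2 ≈ 0.3466; the `<failed, exam>`/`<felt, upset>`
combination is rarer (2 of 6) but its words are perfectly dependent too,
giving (1/3)·ln 3 ≈ 0.3662. The example pair matches the first pattern and
contributes four word-pair features — exactly the semantically incomplete
pairs that motivate patterns as features.

The same stages are scriptable from a shell:

```
causepattern simulate --seed 7 --out synth.jsonl --gold gold.json
causepattern mine --pairs synth.jsonl --min-support 2 --top-frac 0.3 --out patterns.tsv
causepattern train --pairs synth.jsonl --patterns patterns.tsv --out model.json
causepattern predict --model model.json --patterns patterns.tsv --pairs synth.jsonl --out pred.tsv
causepattern evaluate --pairs synth.jsonl --folds 10 --features wp,wp+islp_arm --report report.tsv
```

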