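"""Frequent-set mining and mutual-information scoring of language patterns.

Two mining stages share one Apriori engine:

1. *Intra-sentential* stage: transactions are the cause (or effect) text
   spans, items are content words.  Frequent word sets of size >= 2 whose
   pointwise mutual information

       Conf(lp) = MI(w_1..w_k) = P(w_1..w_k) * ln( P(w_1..w_k) / prod_i P(w_i) )

   clears a confidence threshold become intra-sentential language patterns.
   Probabilities are span-containment frequencies (a word set "occurs" in a
   span when the span contains every word; repeats within one span count
   once), so the model is exactly Apriori's transaction model.

2. *Inter-sentential* stage: transactions are sentence pairs, items are the
   intra patterns matched on either side.  Frequent pattern sets holding at
   least one cause-side and one effect-side pattern, scored by the same MI
   over pair-containment probabilities, become inter-sentential patterns.
   A marginal P(lp) is taken over that pattern's own side's spans.

Candidate generation follows the classical join step (merge frequent
(k-1)-sets sharing their first k-2 items under a canonical lexicographic
item order) and prune step (drop candidates with any infrequent
(k-1)-subset, then count support).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Iterable, Mapping, Sequence

from .records import SentencePairRecord
from .corpus_io import content_words

logger = logging.getLogger(__name__)

__all__ = [
    "FrequentSet",
    "IntraPattern",
    "InterPattern",
    "MiningConfig",
    "support",
    "find_frequent_itemsets",
    "find_frequent_wordsets",
    "intra_confidence",
    "generate_intra_patterns",
    "find_frequent_patternsets",
    "inter_confidence",
    "generate_inter_patterns",
    "select_top_patterns",
    "mine_intra_patterns",
]


@dataclass(frozen=True)
class FrequentSet:
    """An itemset admitted to some L_k, with its transaction support count."""

    items: frozenset
    support: int


@dataclass(frozen=True)
class IntraPattern:
    """A within-span language pattern: k >= 2 words with an MI confidence.

    ``words`` keeps the order of first occurrence in the mined spans (so a
    pattern prints the way it reads); mining itself uses the canonical
    sorted form.  ``side`` tags the span collection the pattern came from.
    """

    words: tuple[str, ...]
    side: str  # "cause" | "effect"
    confidence: float
    support: int = 0

    @property
    def key(self) -> tuple:
        """Canonical identity used as an item in inter-stage mining."""
        return (self.side, tuple(sorted(self.words)))

    def __str__(self) -> str:
        return "<" + ", ".join(self.words) + ">"


@dataclass(frozen=True)
class InterPattern:
    """A cross-boundary pattern: cause-side + effect-side intra patterns."""

    cause_patterns: tuple[IntraPattern, ...]
    effect_patterns: tuple[IntraPattern, ...]
    confidence: float
    support: int = 0

    def __post_init__(self) -> None:
        if not self.cause_patterns or not self.effect_patterns:
            raise ValueError(
                "an inter-sentential pattern needs at least one pattern on each side"
            )

    @property
    def key(self) -> tuple:
        return (
            tuple(sorted(p.key for p in self.cause_patterns)),
            tuple(sorted(p.key for p in self.effect_patterns)),
        )

    def sort_words(self) -> tuple:
        """Deterministic lexicographic tie-break key."""
        return (
            tuple(p.words for p in self.cause_patterns),
            tuple(p.words for p in self.effect_patterns),
        )

    def __str__(self) -> str:
        c = ", ".join(str(p) for p in self.cause_patterns)
        e = ", ".join(str(p) for p in self.effect_patterns)
        return f"<<{c}>, <{e}>>"


@dataclass
class MiningConfig:
    """Support/confidence thresholds for one mining stage.

    Exactly one of ``min_confidence`` (absolute MI threshold, nats) and
    ``top_fraction`` (keep the best fraction of scored patterns) is active.
    ``max_k`` caps the itemset size explored by the Apriori iteration.
    """

    min_support: int = 2
    min_confidence: float | None = 0.0
    top_fraction: float | None = None
    max_k: int = 4

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be a positive integer")
        if (self.min_confidence is None) == (self.top_fraction is None):
            raise ValueError("exactly one of min_confidence / top_fraction must be set")
        if self.top_fraction is not None and not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.max_k < 1:
            raise ValueError("max_k must be positive")


# ---------------------------------------------------------------------------
# Apriori engine
# ---------------------------------------------------------------------------


def support(items: Iterable[Hashable], spans: Sequence[Iterable[Hashable]]) -> int:
    """Number of spans (transactions) containing every item of ``items``."""
    itemset = frozenset(items)
    if not itemset:
        raise ValueError("support of the empty set is undefined")
    return sum(1 for span in spans if itemset <= frozenset(span))


def _count_candidates(
    candidates: set[tuple], transactions: list[frozenset], k: int
) -> dict[tuple, int]:
    """Support counts for sorted candidate tuples of size k.

    Chooses between candidate-driven subset checks and transaction-driven
    k-combination enumeration, whichever touches fewer tuples.
    """
    counts: dict[tuple, int] = {}
    n_combo = sum(math.comb(len(t), k) for t in transactions if len(t) >= k)
    if len(candidates) * len(transactions) <= n_combo:
        for cand in candidates:
            cset = frozenset(cand)
            c = sum(1 for t in transactions if cset <= t)
            if c:
                counts[cand] = c
    else:
        for t in transactions:
            if len(t) < k:
                continue
            for combo in combinations(sorted(t), k):
                if combo in candidates:
                    counts[combo] = counts.get(combo, 0) + 1
    return counts


def find_frequent_itemsets(
    transactions: Sequence[Iterable[Hashable]],
    min_support: int,
    max_k: int | None = None,
) -> dict[int, dict[frozenset, int]]:
    """Apriori over arbitrary hashable, mutually comparable items.

    Returns ``{k: {itemset: support}}`` for every non-empty level L_k.
    L_1 holds the frequent single items; L_k is built from L_{k-1} by the
    join step (merge sets agreeing on their first k-2 items in canonical
    sorted order), the subset-prune step, and a support-count prune.
    Iteration stops when a level comes out empty or ``max_k`` is reached.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    tsets = [frozenset(t) for t in transactions]

    item_counts: dict[Hashable, int] = {}
    for t in tsets:
        for item in t:
            item_counts[item] = item_counts.get(item, 0) + 1
    l1 = {item: c for item, c in item_counts.items() if c >= min_support}
    if not l1:
        return {}
    levels: dict[int, dict[frozenset, int]] = {
        1: {frozenset((item,)): c for item, c in l1.items()}
    }
    # restrict transactions to frequent items: infrequent items can never
    # take part in a frequent superset (anti-monotonicity)
    frequent_items = set(l1)
    tsets = [t & frequent_items for t in tsets]

    prev: dict[tuple, int] = {tuple(sorted(s)): c for s, c in levels[1].items()}
    k = 2
    while prev and (max_k is None or k <= max_k):
        # join step: merge (k-1)-sets with identical first k-2 items
        prev_keys = sorted(prev)
        candidates: set[tuple] = set()
        i = 0
        while i < len(prev_keys):
            j = i
            prefix = prev_keys[i][:-1]
            while j < len(prev_keys) and prev_keys[j][:-1] == prefix:
                j += 1
            group = prev_keys[i:j]
            for a, b in combinations(group, 2):
                candidates.add(a[:-1] + tuple(sorted((a[-1], b[-1]))))
            i = j
        # prune step (subsets): every (k-1)-subset must be frequent
        prev_set = set(prev_keys)
        candidates = {
            cand
            for cand in candidates
            if all(cand[:m] + cand[m + 1 :] in prev_set for m in range(k))
        }
        if not candidates:
            break
        # prune step (support count)
        counts = _count_candidates(candidates, tsets, k)
        lk = {cand: c for cand, c in counts.items() if c >= min_support}
        if not lk:
            break
        levels[k] = {frozenset(cand): c for cand, c in lk.items()}
        prev = lk
        k += 1
    return levels


def find_frequent_wordsets(
    spans: Sequence[Sequence[str]], config: MiningConfig
) -> dict[int, dict[frozenset, int]]:
    """Frequent word sets within a collection of spans (word lists)."""
    return find_frequent_itemsets(spans, config.min_support, config.max_k)


# ---------------------------------------------------------------------------
# Mutual-information confidence
# ---------------------------------------------------------------------------


def _mi(joint: int, marginals: Sequence[int], n: int) -> float:
    """P * ln(P / prod P_i) with counts over n transactions; 0 if joint = 0."""
    if n == 0 or joint == 0:
        return 0.0
    p_joint = joint / n
    denom = 1.0
    for m in marginals:
        if m == 0:
            raise ValueError("every item must occur at least once")
        denom *= m / n
    return p_joint * math.log(p_joint / denom)


def intra_confidence(words: Sequence[str], spans: Sequence[Sequence[str]]) -> float:
    """MI confidence of a word tuple over span-containment probabilities."""
    tsets = [frozenset(s) for s in spans]
    n = len(tsets)
    wset = frozenset(words)
    joint = sum(1 for t in tsets if wset <= t)
    marginals = [sum(1 for t in tsets if w in t) for w in wset]
    return _mi(joint, marginals, n)


def _first_occurrence_order(
    words: frozenset, spans: Sequence[Sequence[str]]
) -> tuple[str, ...]:
    """Order words by their first appearance in the span stream."""
    pos: dict[str, tuple[int, int]] = {}
    remaining = set(words)
    for si, span in enumerate(spans):
        for ti, w in enumerate(span):
            if w in remaining:
                pos[w] = (si, ti)
                remaining.discard(w)
        if not remaining:
            break
    return tuple(sorted(words, key=lambda w: pos.get(w, (len(spans), 0))))


def _apply_confidence_rule(scored: list, config: MiningConfig) -> list:
    """Filter/sort pattern objects (any type with .confidence) per config."""
    scored.sort(key=lambda p: (-p.confidence, p.words if hasattr(p, "words") else p.sort_words()))
    if config.min_confidence is not None:
        return [p for p in scored if p.confidence >= config.min_confidence]
    n_keep = math.ceil(config.top_fraction * len(scored))
    return scored[:n_keep]


def generate_intra_patterns(
    frequent: Mapping[int, Mapping[frozenset, int]],
    spans: Sequence[Sequence[str]],
    config: MiningConfig,
    side: str = "cause",
) -> list[IntraPattern]:
    """Score frequent word sets of size >= 2 and emit those passing the rule.

    Single words are not patterns (a pattern is a meaningful combination of
    words).  Output is sorted by confidence descending, ties broken by the
    pattern's word tuple.
    """
    tsets = [frozenset(s) for s in spans]
    n = len(tsets)
    word_counts: dict[str, int] = {}
    for t in tsets:
        for w in t:
            word_counts[w] = word_counts.get(w, 0) + 1
    scored: list[IntraPattern] = []
    for k, level in frequent.items():
        if k < 2:
            continue
        for itemset, supp in level.items():
            conf = _mi(supp, [word_counts[w] for w in itemset], n)
            scored.append(
                IntraPattern(
                    words=_first_occurrence_order(itemset, spans),
                    side=side,
                    confidence=conf,
                    support=supp,
                )
            )
    return _apply_confidence_rule(scored, config)


def mine_intra_patterns(
    spans: Sequence[Sequence[str]], config: MiningConfig, side: str
) -> list[IntraPattern]:
    """Convenience: frequent word sets + MI filtering in one call."""
    return generate_intra_patterns(find_frequent_wordsets(spans, config), spans, config, side)


# ---------------------------------------------------------------------------
# Inter-sentential stage
# ---------------------------------------------------------------------------


def pattern_span_matches(
    patterns: Sequence[IntraPattern], spans: Sequence[Sequence[str]]
) -> dict[tuple, set[int]]:
    """Span indices containing every word of each pattern (inverted-index join).

    Word comparison is case-folded, so patterns match regardless of the
    capitalization either side carries.
    """
    postings: dict[str, set[int]] = {}
    for i, span in enumerate(spans):
        for w in {w.casefold() for w in span}:
            postings.setdefault(w, set()).add(i)
    matches: dict[tuple, set[int]] = {}
    for pat in patterns:
        lists = [postings.get(w.casefold()) for w in pat.words]
        if any(l is None for l in lists):
            matches[pat.key] = set()
            continue
        lists.sort(key=len)
        acc = set(lists[0])
        for l in lists[1:]:
            acc &= l
            if not acc:
                break
        matches[pat.key] = acc
    return matches


def _pair_transactions(
    cause_patterns: Sequence[IntraPattern],
    effect_patterns: Sequence[IntraPattern],
    pairs: Sequence[SentencePairRecord],
    use_content_words: bool = True,
) -> tuple[list[frozenset], dict[tuple, set[int]]]:
    """Per-pair transactions of matched pattern keys, plus per-side matches."""
    if use_content_words:
        cause_spans = [content_words(p.cause) for p in pairs]
        effect_spans = [content_words(p.effect) for p in pairs]
    else:
        cause_spans = [list(p.cause.surfaces) for p in pairs]
        effect_spans = [list(p.effect.surfaces) for p in pairs]
    matches = pattern_span_matches(cause_patterns, cause_spans)
    matches.update(pattern_span_matches(effect_patterns, effect_spans))
    per_pair: list[set] = [set() for _ in pairs]
    for key, idxs in matches.items():
        for i in idxs:
            per_pair[i].add(key)
    return [frozenset(s) for s in per_pair], matches


def find_frequent_patternsets(
    cause_patterns: Sequence[IntraPattern],
    effect_patterns: Sequence[IntraPattern],
    pairs: Sequence[SentencePairRecord],
    config: MiningConfig,
) -> list[FrequentSet]:
    """Frequent cross-boundary pattern sets (>= 1 pattern from each side).

    A pair "contains" a pattern when every pattern word occurs in the span
    on the pattern's side; support is the number of pairs containing all
    patterns of the set.  Mining reuses the same join/prune iteration with
    intra patterns as items; sets lying entirely on one side are discarded.
    """
    if not cause_patterns or not effect_patterns:
        logger.warning("no intra-sentential patterns on one side; no pattern sets mined")
        return []
    transactions, _ = _pair_transactions(cause_patterns, effect_patterns, pairs)
    levels = find_frequent_itemsets(transactions, config.min_support, config.max_k)
    out: list[FrequentSet] = []
    for k, level in levels.items():
        if k < 2:
            continue
        for itemset, supp in level.items():
            sides = {side for side, _ in itemset}
            if sides == {"cause", "effect"}:
                out.append(FrequentSet(items=itemset, support=supp))
    return out


def inter_confidence(
    patterns: Sequence[IntraPattern], pairs: Sequence[SentencePairRecord]
) -> float:
    """MI confidence of a pattern tuple over pair-containment probabilities.

    The joint probability counts pairs containing every pattern on its own
    side; each marginal P(lp) counts the pattern's occurrences in its own
    side's spans.  Both are normalized by the number of pairs (each pair
    contributes one cause span and one effect span).
    """
    cause_pats = [p for p in patterns if p.side == "cause"]
    effect_pats = [p for p in patterns if p.side == "effect"]
    transactions, matches = _pair_transactions(cause_pats, effect_pats, pairs)
    n = len(pairs)
    keys = [p.key for p in patterns]
    joint = sum(1 for t in transactions if all(k in t for k in set(keys)))
    marginals = [len(matches[k]) for k in dict.fromkeys(keys)]
    return _mi(joint, marginals, n)


def generate_inter_patterns(
    cause_patterns: Sequence[IntraPattern],
    effect_patterns: Sequence[IntraPattern],
    pairs: Sequence[SentencePairRecord],
    config: MiningConfig,
) -> list[InterPattern]:
    """Mine, score, and threshold inter-sentential patterns in one pass."""
    if not cause_patterns or not effect_patterns:
        logger.warning("no intra-sentential patterns on one side; no inter patterns")
        return []
    transactions, matches = _pair_transactions(cause_patterns, effect_patterns, pairs)
    levels = find_frequent_itemsets(transactions, config.min_support, config.max_k)
    by_key = {p.key: p for p in list(cause_patterns) + list(effect_patterns)}
    n = len(pairs)
    scored: list[InterPattern] = []
    for k, level in levels.items():
        if k < 2:
            continue
        for itemset, supp in level.items():
            sides = {side for side, _ in itemset}
            if sides != {"cause", "effect"}:
                continue
            pats = [by_key[key] for key in sorted(itemset)]
            conf = _mi(supp, [len(matches[p.key]) for p in pats], n)
            scored.append(
                InterPattern(
                    cause_patterns=tuple(p for p in pats if p.side == "cause"),
                    effect_patterns=tuple(p for p in pats if p.side == "effect"),
                    confidence=conf,
                    support=supp,
                )
            )
    return _apply_confidence_rule(scored, config)


def select_top_patterns(patterns: Sequence[InterPattern], fraction: float) -> list[InterPattern]:
    """Keep the top ``ceil(fraction * count)`` patterns by confidence.

    Patterns are sorted by confidence descending with lexicographic word
    tie-breaks, so the selection is deterministic.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    ordered = sorted(patterns, key=lambda p: (-p.confidence, p.sort_words()))
    if not ordered:
        return []
    return ordered[: math.ceil(fraction * len(ordered))]
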