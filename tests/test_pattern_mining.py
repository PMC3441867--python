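"""Apriori word-set mining and MI confidence scoring, checked against
brute-force enumeration oracles."""

import logging
import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from causepattern.pattern_mining import (
    FrequentSet,
    InterPattern,
    IntraPattern,
    MiningConfig,
    find_frequent_patternsets,
    find_frequent_wordsets,
    generate_inter_patterns,
    generate_intra_patterns,
    inter_confidence,
    intra_confidence,
    select_top_patterns,
    support,
)

from conftest import make_pair


def brute_force_frequent_sets(spans, min_support, max_k):
    """Independent oracle: enumerate every subset of every span directly."""
    counts = {}
    for span in spans:
        sset = frozenset(span)
        for k in range(1, min(len(sset), max_k) + 1):
            for combo in combinations(sorted(sset), k):
                counts[frozenset(combo)] = counts.get(frozenset(combo), 0) + 1
    levels = {}
    for itemset, c in counts.items():
        if c >= min_support:
            levels.setdefault(len(itemset), {})[itemset] = c
    return levels


corpora = st.lists(
    st.lists(st.sampled_from([f"w{i}" for i in range(12)]), max_size=8),
    min_size=1,
    max_size=30,
)


# --- support ----------------------------------------------------------------


def test_support_counts_spans_containing_all_items():
    spans = [["broke_up", "boyfriend"], ["failed"], ["broke_up", "boyfriend", "quarrel"]]
    assert support({"broke_up", "boyfriend"}, spans) == 2
    assert support({"failed"}, spans) == 1


def test_support_over_empty_span_list_is_zero():
    assert support({"x"}, []) == 0


def test_repeated_words_within_a_span_count_once():
    assert support({"a"}, [["a", "a", "a"], ["b"]]) == 1


@given(corpora, st.integers(0, 11), st.integers(0, 11))
def test_support_is_anti_monotone(spans, i, j):
    """Adding an item to a set can never raise its support."""
    small = {f"w{i}"}
    large = small | {f"w{j}"}
    assert support(small, spans) >= support(large, spans)


# --- Apriori ----------------------------------------------------------------


def test_worked_apriori_example():
    spans = [["a", "b", "c"], ["a", "b"], ["a", "c"], ["d"]]
    levels = find_frequent_wordsets(spans, MiningConfig(min_support=2))
    assert levels[1] == {
        frozenset("a"): 3,
        frozenset("b"): 2,
        frozenset("c"): 2,
    }
    assert levels[2] == {frozenset(["a", "b"]): 2, frozenset(["a", "c"]): 2}
    # {a,b,c} is pruned: its subset {b,c} has support 1
    assert 3 not in levels


def test_min_support_above_corpus_size_gives_nothing():
    spans = [["a", "b"], ["a"]]
    assert find_frequent_wordsets(spans, MiningConfig(min_support=3)) == {}


@settings(max_examples=60)
@given(corpora, st.integers(1, 3))
def test_apriori_matches_brute_force(spans, min_support):
    cfg = MiningConfig(min_support=min_support, max_k=4)
    assert find_frequent_wordsets(spans, cfg) == brute_force_frequent_sets(
        spans, min_support, 4
    )


def test_max_k_caps_the_iteration():
    spans = [["a", "b", "c", "d"]] * 3
    levels = find_frequent_wordsets(spans, MiningConfig(min_support=2, max_k=2))
    assert set(levels) == {1, 2}


# --- MI confidence ----------------------------------------------------------


def test_two_word_mi_hand_value():
    # 4 spans; each word in 2, co-occurring in 2: 0.5 * ln(0.5 / 0.25)
    spans = [["u", "v"], ["u", "v"], ["x"], ["y"]]
    assert intra_confidence(("u", "v"), spans) == pytest.approx(0.5 * math.log(2), abs=1e-9)


def test_three_word_mi_hand_value():
    # all three words always together in 2 of 4 spans: 0.5 * ln(0.5 / 0.125)
    spans = [["u", "v", "w"], ["u", "v", "w"], ["x"], ["y"]]
    assert intra_confidence(("u", "v", "w"), spans) == pytest.approx(
        0.5 * math.log(4), abs=1e-9
    )


def test_independent_words_score_exactly_zero():
    # joint frequency equals product of marginals: 1/4 = (1/2)(1/2)
    spans = [["u", "v"], ["u"], ["v"], ["z"]]
    assert intra_confidence(("u", "v"), spans) == 0.0


def test_zero_joint_support_returns_zero():
    spans = [["u"], ["v"]]
    assert intra_confidence(("u", "v"), spans) == 0.0


@given(corpora)
def test_mi_is_positive_iff_joint_exceeds_product(spans):
    words = ("w0", "w1")
    n = len(spans)
    joint = support(set(words), spans)
    if joint == 0 or any(support({w}, spans) == 0 for w in words):
        return
    prod = math.prod(support({w}, spans) / n for w in words)
    mi = intra_confidence(words, spans)
    if joint / n > prod:
        assert mi > 0
    elif math.isclose(joint / n, prod):
        assert mi == pytest.approx(0.0, abs=1e-12)
    else:
        assert mi < 0


# --- intra pattern generation -----------------------------------------------


def test_infinite_threshold_gives_no_patterns():
    spans = [["a", "b"]] * 4
    cfg = MiningConfig(min_support=2, min_confidence=math.inf)
    pats = generate_intra_patterns(find_frequent_wordsets(spans, cfg), spans, cfg)
    assert pats == []


def test_single_words_are_not_patterns():
    spans = [["a"]] * 5
    cfg = MiningConfig(min_support=2, min_confidence=-math.inf)
    pats = generate_intra_patterns(find_frequent_wordsets(spans, cfg), spans, cfg)
    assert pats == []


def test_pattern_words_keep_first_occurrence_order():
    # "broke_up" precedes "boyfriend" in the spans although it sorts after it
    spans = [["broke_up", "boyfriend"], ["broke_up", "boyfriend"], ["x"], ["y"]]
    cfg = MiningConfig(min_support=2, min_confidence=0.0)
    pats = generate_intra_patterns(find_frequent_wordsets(spans, cfg), spans, cfg, "cause")
    assert [p.words for p in pats] == [("broke_up", "boyfriend")]


@settings(max_examples=40)
@given(corpora, st.floats(0.0, 0.3))
def test_emitted_patterns_equal_brute_force_mi_filter(spans, threshold):
    cfg = MiningConfig(min_support=2, min_confidence=threshold, max_k=4)
    pats = generate_intra_patterns(find_frequent_wordsets(spans, cfg), spans, cfg)
    expected = {
        itemset
        for k, level in brute_force_frequent_sets(spans, 2, 4).items()
        if k >= 2
        for itemset in level
        if intra_confidence(tuple(itemset), spans) >= threshold
    }
    assert {frozenset(p.words) for p in pats} == expected
    confs = [p.confidence for p in pats]
    assert confs == sorted(confs, reverse=True)


# --- inter stage ------------------------------------------------------------


def _intra(words, side):
    return IntraPattern(words=tuple(words), side=side, confidence=1.0)


def fig1b_like_pairs():
    """Pairs where <broke_up, boyfriend> and <life, meaningless> co-occur."""
    pairs = []
    for i in range(3):
        pairs.append(
            make_pair(f"c{i}", ["broke_up", "boyfriend", f"f{i}"], ["life", "meaningless"])
        )
    pairs.append(make_pair("c3", ["failed", "exam"], ["felt", "upset"]))
    pairs.append(make_pair("c4", ["failed", "exam"], ["felt", "upset"]))
    pairs.append(make_pair("c5", ["weather"], ["home"]))
    return pairs


def test_co_occurring_patterns_become_a_frequent_set():
    pairs = fig1b_like_pairs()
    cause_pats = [_intra(("broke_up", "boyfriend"), "cause"), _intra(("failed", "exam"), "cause")]
    effect_pats = [_intra(("life", "meaningless"), "effect"), _intra(("felt", "upset"), "effect")]
    cfg = MiningConfig(min_support=2)
    freq = find_frequent_patternsets(cause_pats, effect_pats, pairs, cfg)
    found = {frozenset((c.key, e.key)) for c, e in [(cause_pats[0], effect_pats[0]), (cause_pats[1], effect_pats[1])]}
    assert {fs.items for fs in freq} == found
    supports = {fs.items: fs.support for fs in freq}
    assert supports[frozenset((cause_pats[0].key, effect_pats[0].key))] == 3


def test_min_support_above_pair_count_gives_no_pattern_sets():
    pairs = fig1b_like_pairs()
    cfg = MiningConfig(min_support=10)
    assert find_frequent_patternsets(
        [_intra(("broke_up", "boyfriend"), "cause")],
        [_intra(("life", "meaningless"), "effect")],
        pairs,
        cfg,
    ) == []


def test_missing_side_yields_empty_with_warning(caplog):
    with caplog.at_level(logging.WARNING):
        out = find_frequent_patternsets([], [_intra(("a", "b"), "effect")], [], MiningConfig())
    assert out == []
    assert any("one side" in r.message for r in caplog.records)


def test_patternset_mining_matches_brute_force_on_small_inventory():
    rng = np.random.default_rng(7)
    vocab_c = [f"c{i}" for i in range(6)]
    vocab_e = [f"e{i}" for i in range(6)]
    pairs = [
        make_pair(
            f"r{i}",
            list(rng.choice(vocab_c, size=3, replace=False)),
            list(rng.choice(vocab_e, size=3, replace=False)),
        )
        for i in range(20)
    ]
    cause_pats = [_intra((a, b), "cause") for a, b in combinations(vocab_c[:4], 2)]
    effect_pats = [_intra((a, b), "effect") for a, b in combinations(vocab_e[:4], 2)][:2]
    cfg = MiningConfig(min_support=2, max_k=3)
    mined = {fs.items: fs.support for fs in find_frequent_patternsets(cause_pats, effect_pats, pairs, cfg)}

    # oracle: enumerate every cross-side pattern combination directly
    def contains(pair, pat):
        span = pair.cause if pat.side == "cause" else pair.effect
        return set(pat.words) <= set(s.surface for s in span.tokens)

    expected = {}
    allp = cause_pats + effect_pats
    for k in (2, 3):
        for combo in combinations(allp, k):
            sides = {p.side for p in combo}
            if sides != {"cause", "effect"}:
                continue
            supp = sum(1 for pr in pairs if all(contains(pr, p) for p in combo))
            if supp >= 2:
                expected[frozenset(p.key for p in combo)] = supp
    assert mined == expected


def test_inter_confidence_hand_value():
    # 4 pairs; each side pattern in 2 spans, co-occurring in 2 pairs
    pairs = [
        make_pair("a", ["u", "v"], ["x", "y"]),
        make_pair("b", ["u", "v"], ["x", "y"]),
        make_pair("c", ["z"], ["q"]),
        make_pair("d", ["w"], ["r"]),
    ]
    pats = (_intra(("u", "v"), "cause"), _intra(("x", "y"), "effect"))
    assert inter_confidence(pats, pairs) == pytest.approx(0.5 * math.log(2), abs=1e-9)


def test_inter_confidence_zero_under_independence():
    # cause pattern in pairs {a,b}, effect pattern in {a,c}: joint 1/4 = 1/2 * 1/2
    pairs = [
        make_pair("a", ["u", "v"], ["x", "y"]),
        make_pair("b", ["u", "v"], ["q"]),
        make_pair("c", ["z"], ["x", "y"]),
        make_pair("d", ["w"], ["r"]),
    ]
    pats = (_intra(("u", "v"), "cause"), _intra(("x", "y"), "effect"))
    assert inter_confidence(pats, pairs) == 0.0


def test_generated_inter_ranking_matches_brute_force():
    pairs = fig1b_like_pairs()
    cause_pats = [_intra(("broke_up", "boyfriend"), "cause"), _intra(("failed", "exam"), "cause")]
    effect_pats = [_intra(("life", "meaningless"), "effect"), _intra(("felt", "upset"), "effect")]
    cfg = MiningConfig(min_support=2, min_confidence=-math.inf, max_k=2)
    mined = generate_inter_patterns(cause_pats, effect_pats, pairs, cfg)
    oracle = sorted(
        (
            (inter_confidence((c, e), pairs), c.key, e.key)
            for c in cause_pats
            for e in effect_pats
            if sum(
                1
                for pr in pairs
                if set(c.words) <= set(pr.cause.surfaces)
                and set(e.words) <= set(pr.effect.surfaces)
            )
            >= 2
        ),
        key=lambda t: -t[0],
    )
    assert [(p.cause_patterns[0].key, p.effect_patterns[0].key) for p in mined] == [
        (c, e) for _, c, e in oracle
    ]
    assert [p.confidence for p in mined] == pytest.approx([t[0] for t in oracle])


# --- top-fraction selection -------------------------------------------------


def _inter_with_conf(i, conf):
    return InterPattern(
        cause_patterns=(_intra((f"c{i}", f"c{i}x"), "cause"),),
        effect_patterns=(_intra((f"e{i}", f"e{i}x"), "effect"),),
        confidence=conf,
    )


@pytest.mark.parametrize("fraction, expected_count", [(0.3, 3), (0.7, 7), (1.0, 10)])
def test_top_fraction_counts(fraction, expected_count):
    patterns = [_inter_with_conf(i, conf=i / 10) for i in range(10)]
    top = select_top_patterns(patterns, fraction)
    assert len(top) == expected_count
    confs = [p.confidence for p in top]
    assert confs == sorted(confs, reverse=True)


def test_selection_is_a_prefix_and_monotone_in_fraction():
    patterns = [_inter_with_conf(i, conf=(i * 7) % 10 / 10) for i in range(9)]
    full = select_top_patterns(patterns, 1.0)
    prev_len = 0
    for frac in (0.1, 0.25, 0.5, 0.75, 1.0):
        sel = select_top_patterns(patterns, frac)
        assert sel == full[: len(sel)]  # always a prefix of the sorted list
        assert len(sel) >= prev_len
        prev_len = len(sel)


def test_empty_input_gives_empty_selection():
    assert select_top_patterns([], 0.5) == []


def test_ties_break_lexicographically():
    a = _inter_with_conf(2, 0.5)
    b = _inter_with_conf(1, 0.5)
    assert select_top_patterns([a, b], 1.0) == [b, a]
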