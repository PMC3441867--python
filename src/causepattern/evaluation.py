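"""Evaluation harness: metrics, cross-validation, sweeps, significance.

Recall, precision and F-measure treat "causality" as the positive class:

    Recall    = TP / (TP + FN)
    Precision = TP / (TP + FP)
    F         = 2 R P / (R + P)

with the degenerate conventions R = P = F = 0 when a denominator is zero.

k-fold cross-validation is stratified and seeded; inside every fold the
pattern inventories are re-mined from that fold's training split only, so no
test pair ever influences pattern discovery or probability estimation (this
is asserted, not assumed).  Feature sets under comparison: ``wp`` (word
pairs alone), ``wp+islp_arm`` (adding inter patterns mined by extended
association rule mining), and ``wp+islp_parsing`` (adding inter patterns
built from dependency-parse word/head pairs, available when parses are
supplied).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .causality_classifier import Prediction, featurize_many, predict, train
from .corpus_io import content_words
from .dependency_patterns import ParsedSpan, dependency_intra_patterns
from .pattern_mining import (
    InterPattern,
    MiningConfig,
    generate_inter_patterns,
    mine_intra_patterns,
    select_top_patterns,
)
from .records import SentencePairRecord

logger = logging.getLogger(__name__)

__all__ = [
    "EvalResult",
    "PipelineConfig",
    "TTestResult",
    "FEATURE_SETS",
    "score",
    "mine_inventory",
    "run_pipeline",
    "stratified_folds",
    "kfold_cv",
    "compare_feature_sets",
    "sweep",
]

FEATURE_SETS = ("wp", "wp+islp_arm", "wp+islp_parsing")


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts plus the derived retrieval metrics."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def f_measure(self) -> float:
        r, p = self.recall, self.precision
        return 2 * r * p / (r + p) if (r + p) else 0.0


def score(predictions: Mapping[str, str], gold: Mapping[str, str]) -> EvalResult:
    """Confusion counts of predicted vs gold labels, aligned by record id."""
    if set(predictions) != set(gold):
        missing = set(gold) ^ set(predictions)
        raise ValueError(f"prediction/gold id mismatch on {sorted(missing)[:5]} ...")
    tp = fp = fn = tn = 0
    for rid, pred in predictions.items():
        g = gold[rid]
        if pred == "causality" and g == "causality":
            tp += 1
        elif pred == "causality":
            fp += 1
        elif g == "causality":
            fn += 1
        else:
            tn += 1
    return EvalResult(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class PipelineConfig:
    """End-to-end settings for mining + classification.

    ``min_support`` and ``intra_min_confidence`` gate the intra stage;
    ``top_fraction`` selects the best fraction of scored inter patterns
    (the knob the experiments tune); ``inter_max_k`` caps how many intra
    patterns one inter pattern combines (2 = one per side).
    """

    min_support: int = 2
    intra_min_confidence: float = 0.01
    intra_max_k: int = 4
    inter_max_k: int = 2
    top_fraction: float = 0.3
    smoothing: str = "add-one"
    content_only: bool = True

    def intra_config(self) -> MiningConfig:
        return MiningConfig(
            min_support=self.min_support,
            min_confidence=self.intra_min_confidence,
            max_k=self.intra_max_k,
        )

    def inter_config(self) -> MiningConfig:
        return MiningConfig(
            min_support=self.min_support,
            min_confidence=None,
            top_fraction=self.top_fraction,
            max_k=self.inter_max_k,
        )


def mine_inventory(
    train_pairs: Sequence[SentencePairRecord],
    config: PipelineConfig,
    method: str = "arm",
    parses: Mapping[str, ParsedSpan] | None = None,
) -> list[InterPattern]:
    """Mine the inter-pattern inventory from the causality training pairs.

    ``method`` selects how intra patterns are produced: ``"arm"`` (frequent
    word sets) or ``"parsing"`` (dependency word/head pairs, requiring
    ``parses`` keyed by ``<record-id>/<side>``).  The inter stage and the
    top-fraction selection are identical for both.
    """
    causal = [p for p in train_pairs if p.label == "causality"]
    if not causal:
        logger.warning("no causality pairs in the mining corpus; empty inventory")
        return []
    cause_spans = [content_words(p.cause) for p in causal]
    effect_spans = [content_words(p.effect) for p in causal]
    icfg = config.intra_config()
    if method == "arm":
        cause_pats = mine_intra_patterns(cause_spans, icfg, "cause")
        effect_pats = mine_intra_patterns(effect_spans, icfg, "effect")
    elif method == "parsing":
        if parses is None:
            raise ValueError("method 'parsing' requires dependency parses")
        cause_parses = [
            parses[f"{p.id}/cause"] for p in causal if f"{p.id}/cause" in parses
        ]
        effect_parses = [
            parses[f"{p.id}/effect"] for p in causal if f"{p.id}/effect" in parses
        ]
        cause_pats = dependency_intra_patterns(cause_parses, cause_spans, icfg, "cause")
        effect_pats = dependency_intra_patterns(effect_parses, effect_spans, icfg, "effect")
    else:
        raise ValueError(f"unknown intra-pattern method {method!r}")
    inter = generate_inter_patterns(cause_pats, effect_pats, causal, config.inter_config())
    return inter


def run_pipeline(
    train_pairs: Sequence[SentencePairRecord],
    test_pairs: Sequence[SentencePairRecord],
    feature_set: str = "wp+islp_arm",
    config: PipelineConfig | None = None,
    parses: Mapping[str, ParsedSpan] | None = None,
) -> dict[str, Prediction]:
    """Mine patterns, train the classifier, and predict the test pairs."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    config = config or PipelineConfig()
    if feature_set == "wp":
        inventory: list[InterPattern] = []
    else:
        method = "arm" if feature_set.endswith("arm") else "parsing"
        inventory = mine_inventory(train_pairs, config, method=method, parses=parses)
    train_feats = featurize_many(train_pairs, inventory, config.content_only)
    test_feats = featurize_many(test_pairs, inventory, config.content_only)
    model = train(train_pairs, train_feats, smoothing=config.smoothing)
    return {
        pair.id: predict(model, feats) for pair, feats in zip(test_pairs, test_feats)
    }


def stratified_folds(
    pairs: Sequence[SentencePairRecord], k: int, seed: int
) -> list[list[str]]:
    """Deterministic stratified fold assignment; returns k lists of ids.

    Ids are shuffled within each class with a seeded generator and dealt
    round-robin, so every fold carries (near-)proportional class counts.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    pos = 0  # carried across classes so fold sizes stay balanced
    for label in ("causality", "non-causality", "unlabeled"):
        ids = [p.id for p in pairs if p.label == label]
        for idx in rng.permutation(len(ids)):
            folds[pos % k].append(ids[idx])
            pos += 1
    return [sorted(f) for f in folds]


@dataclass
class CVResult:
    """Per-fold results plus their arithmetic mean."""

    folds: list[EvalResult]

    @property
    def mean_recall(self) -> float:
        return float(np.mean([f.recall for f in self.folds]))

    @property
    def mean_precision(self) -> float:
        return float(np.mean([f.precision for f in self.folds]))

    @property
    def mean_f(self) -> float:
        return float(np.mean([f.f_measure for f in self.folds]))


def kfold_cv(
    pairs: Sequence[SentencePairRecord],
    k: int,
    feature_set: str = "wp+islp_arm",
    config: PipelineConfig | None = None,
    seed: int = 13,
    parses: Mapping[str, ParsedSpan] | None = None,
    train_fraction: float = 1.0,
) -> CVResult:
    """Stratified k-fold cross-validation of the full pipeline.

    Pattern mining and probability estimation inside each fold see only
    that fold's training split (id-disjointness is asserted).  With
    ``train_fraction`` < 1 the training split is stratified-subsampled, for
    learning-curve sweeps.
    """
    labeled = [p for p in pairs if p.label in ("causality", "non-causality")]
    by_id = {p.id: p for p in labeled}
    folds = stratified_folds(labeled, k, seed)
    for fold_ids in folds:
        if not any(by_id[i].label == "causality" for i in fold_ids) or not any(
            by_id[i].label == "non-causality" for i in fold_ids
        ):
            raise ValueError("a fold is missing one class; use fewer folds or more data")
    rng = np.random.default_rng(seed + 1)
    results: list[EvalResult] = []
    for fi, fold_ids in enumerate(folds):
        test_ids = set(fold_ids)
        train_recs = [p for p in labeled if p.id not in test_ids]
        test_recs = [by_id[i] for i in fold_ids]
        assert not ({p.id for p in train_recs} & test_ids), "train/test leakage"
        if train_fraction < 1.0:
            kept: list[SentencePairRecord] = []
            for label in ("causality", "non-causality"):
                cls = [p for p in train_recs if p.label == label]
                n_keep = max(1, int(round(train_fraction * len(cls))))
                order = rng.permutation(len(cls))[:n_keep]
                kept.extend(cls[i] for i in sorted(order))
            train_recs = kept
        preds = run_pipeline(train_recs, test_recs, feature_set, config, parses)
        results.append(
            score(
                {rid: p.label for rid, p in preds.items()},
                {p.id: p.label for p in test_recs},
            )
        )
    return CVResult(folds=results)


@dataclass(frozen=True)
class TTestResult:
    """Paired two-tailed t-test on per-fold F-measures."""

    t: float
    p: float
    mean_diff: float
    degenerate: bool = False  # zero-variance nonzero difference


def compare_feature_sets(
    fold_results_a: Sequence[EvalResult], fold_results_b: Sequence[EvalResult]
) -> TTestResult:
    """Paired two-tailed t-test between two feature sets' per-fold F values.

    Identical fold lists give t = 0, p = 1.  A constant nonzero difference
    has zero variance, making the statistic undefined; it is reported as
    significant (t = +/-inf, p = 0) with ``degenerate=True``.
    """
    if len(fold_results_a) != len(fold_results_b):
        raise ValueError("fold lists must be paired (equal length)")
    if len(fold_results_a) < 2:
        raise ValueError("need at least two folds for a paired t-test")
    a = np.array([f.f_measure for f in fold_results_a])
    b = np.array([f.f_measure for f in fold_results_b])
    diff = a - b
    mean_diff = float(diff.mean())
    if np.allclose(diff.std(ddof=1), 0.0):
        if math.isclose(mean_diff, 0.0, abs_tol=1e-15):
            return TTestResult(t=0.0, p=1.0, mean_diff=0.0)
        return TTestResult(
            t=math.copysign(math.inf, mean_diff), p=0.0, mean_diff=mean_diff, degenerate=True
        )
    res = stats.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), mean_diff=mean_diff)


def sweep(
    pairs: Sequence[SentencePairRecord],
    axis: str,
    settings: Sequence[float],
    feature_sets: Sequence[str],
    k: int = 10,
    config: PipelineConfig | None = None,
    seed: int = 13,
    parses: Mapping[str, ParsedSpan] | None = None,
) -> pd.DataFrame:
    """Mean CV performance along a parameter axis for several feature sets.

    ``axis`` is ``"training-fraction"`` (how much of each fold's training
    split is used) or ``"top-fraction"`` (what share of scored inter
    patterns enters the inventory).  Returns one row per
    (setting, feature set) with mean recall/precision/F across folds.
    """
    if axis not in ("training-fraction", "top-fraction"):
        raise ValueError("axis must be 'training-fraction' or 'top-fraction'")
    settings = list(settings)
    if any(not (0 < s <= 1) for s in settings):
        raise ValueError("settings must lie in (0, 1]")
    if sorted(settings) != settings:
        raise ValueError("settings must be strictly increasing")
    config = config or PipelineConfig()
    rows = []
    for setting in settings:
        for fs in feature_sets:
            if axis == "training-fraction":
                cv = kfold_cv(pairs, k, fs, config, seed, parses, train_fraction=setting)
            else:
                cfg = replace(config, top_fraction=setting)
                cv = kfold_cv(pairs, k, fs, cfg, seed, parses)
            rows.append(
                {
                    "axis": axis,
                    "setting": setting,
                    "feature_set": fs,
                    "mean_recall": cv.mean_recall,
                    "mean_precision": cv.mean_precision,
                    "mean_f": cv.mean_f,
                }
            )
    return pd.DataFrame(rows)
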