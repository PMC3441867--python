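"""Probabilistic causality detection from pattern and word-pair features.

A sentence pair (s_i, s_j) is classified as causality / non-causality by

    c* = argmax_c  prod_i P(islp_i | c)  prod_{(w_i,w_j)} P((w_i,w_j) | c)  P(c)

where the first product runs over the inter-sentential language patterns the
pair matches and the second over its word pairs (cross product of cause-side
and effect-side content words).  Conditional probabilities are relative
frequencies over training pairs, P(f|c) = N(f,c)/N(c), with the class prior
P(c) = N(c)/N.

As printed, a single unseen feature zeroes the whole product, so add-one
smoothing over the training feature vocabulary is applied by default:
P(f|c) = (N(f,c)+1)/(N(c)+|V|), with each feature family (patterns, word
pairs) smoothed against its own vocabulary; features never seen in training
receive the same smoothed floor.  ``smoothing="none"`` reproduces the bare
relative frequencies and simply ignores zero-count features.  All scoring is
done in the log domain, and an exact tie is resolved to non-causality (the
conservative default for a detector).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus_io import content_words
from .pattern_mining import InterPattern, pattern_span_matches
from .records import SentencePairRecord

__all__ = [
    "FeatureRepresentation",
    "CausalityModel",
    "Prediction",
    "featurize",
    "featurize_many",
    "train",
    "predict",
    "save_model",
    "load_model",
]

CLASSES = ("causality", "non-causality")


@dataclass(frozen=True)
class FeatureRepresentation:
    """The feature view of one sentence pair.

    ``islp_matches`` holds the keys of inter patterns whose cause-side words
    all occur in the cause span and effect-side words all in the effect
    span; ``word_pairs`` is the cross product of cause x effect content
    words.  Both are sets: a feature matched several times in one pair
    counts once.
    """

    islp_matches: frozenset
    word_pairs: frozenset


def _span_words(pair: SentencePairRecord, side: str, content_only: bool) -> list[str]:
    span = pair.cause if side == "cause" else pair.effect
    if content_only:
        return content_words(span)
    return [s.casefold() for s in span.surfaces]


def featurize(
    pair: SentencePairRecord,
    patterns: Sequence[InterPattern],
    content_only: bool = True,
) -> FeatureRepresentation:
    """Feature representation of a single pair against a pattern inventory."""
    return featurize_many([pair], patterns, content_only)[0]


def featurize_many(
    pairs: Sequence[SentencePairRecord],
    patterns: Sequence[InterPattern],
    content_only: bool = True,
) -> list[FeatureRepresentation]:
    """Vectorized featurization (pattern matching via an inverted index)."""
    cause_spans = [_span_words(p, "cause", content_only) for p in pairs]
    effect_spans = [_span_words(p, "effect", content_only) for p in pairs]

    intra_cause = {ip.key: ip for pat in patterns for ip in pat.cause_patterns}
    intra_effect = {ip.key: ip for pat in patterns for ip in pat.effect_patterns}
    cause_hits = pattern_span_matches(list(intra_cause.values()), cause_spans)
    effect_hits = pattern_span_matches(list(intra_effect.values()), effect_spans)

    matched: list[set] = [set() for _ in pairs]
    for pat in patterns:
        idx: set[int] | None = None
        for ip in pat.cause_patterns:
            hits = cause_hits[ip.key]
            idx = set(hits) if idx is None else idx & hits
        for ip in pat.effect_patterns:
            idx = idx & effect_hits[ip.key] if idx is not None else set(effect_hits[ip.key])
        for i in idx or ():
            matched[i].add(pat.key)

    out = []
    for i in range(len(pairs)):
        wps = {(wc, we) for wc in set(cause_spans[i]) for we in set(effect_spans[i])}
        out.append(
            FeatureRepresentation(
                islp_matches=frozenset(matched[i]), word_pairs=frozenset(wps)
            )
        )
    return out


def _freeze(key):
    """JSON-stable encoding of a feature key."""
    return json.dumps(key, sort_keys=True)


@dataclass
class CausalityModel:
    """Counts and priors backing the factored classifier.

    Stores raw counts rather than probabilities so both smoothing modes can
    be evaluated from one trained model.
    """

    class_counts: dict[str, int]
    islp_counts: dict[str, dict[str, int]]  # class -> frozen feature key -> count
    wp_counts: dict[str, dict[str, int]]
    islp_vocab: list[str]
    wp_vocab: list[str]
    smoothing: str = "add-one"  # "add-one" | "none"
    version: int = 1

    @property
    def n_total(self) -> int:
        return sum(self.class_counts.values())

    def prior(self, cls: str) -> float:
        return self.class_counts[cls] / self.n_total

    def feature_prob(self, family: str, key: str, cls: str) -> float | None:
        """Smoothed P(feature | class); ``None`` when the feature is ignored."""
        counts = self.islp_counts if family == "islp" else self.wp_counts
        vocab_size = len(self.islp_vocab if family == "islp" else self.wp_vocab)
        n_c = self.class_counts[cls]
        c = counts[cls].get(key, 0)
        if self.smoothing == "add-one":
            return (c + 1) / (n_c + vocab_size)
        if c == 0:
            return None  # unsmoothed zero-count features are ignored
        return c / n_c


@dataclass(frozen=True)
class Prediction:
    """Predicted label plus the per-class log scores behind it."""

    label: str
    log_scores: dict[str, float] = field(compare=False)


def train(
    pairs: Sequence[SentencePairRecord],
    features: Sequence[FeatureRepresentation],
    smoothing: str = "add-one",
) -> CausalityModel:
    """Estimate the probability tables from labeled, featurized pairs."""
    if smoothing not in ("add-one", "none"):
        raise ValueError(f"unknown smoothing mode {smoothing!r}")
    if len(pairs) != len(features):
        raise ValueError("pairs and features must align one-to-one")
    class_counts = {c: 0 for c in CLASSES}
    islp_counts: dict[str, dict[str, int]] = {c: {} for c in CLASSES}
    wp_counts: dict[str, dict[str, int]] = {c: {} for c in CLASSES}
    islp_vocab: set[str] = set()
    wp_vocab: set[str] = set()
    for pair, feats in zip(pairs, features):
        if pair.label not in CLASSES:
            raise ValueError(f"record {pair.id!r} is unlabeled; cannot train on it")
        cls = pair.label
        class_counts[cls] += 1
        for key in feats.islp_matches:
            fk = _freeze(key)
            islp_counts[cls][fk] = islp_counts[cls].get(fk, 0) + 1
            islp_vocab.add(fk)
        for key in feats.word_pairs:
            fk = _freeze(list(key))
            wp_counts[cls][fk] = wp_counts[cls].get(fk, 0) + 1
            wp_vocab.add(fk)
    if min(class_counts.values()) == 0:
        raise ValueError("training data must contain at least one pair of each class")
    return CausalityModel(
        class_counts=class_counts,
        islp_counts=islp_counts,
        wp_counts=wp_counts,
        islp_vocab=sorted(islp_vocab),
        wp_vocab=sorted(wp_vocab),
        smoothing=smoothing,
    )


def predict(model: CausalityModel, features: FeatureRepresentation) -> Prediction:
    """Log-domain argmax over the two classes; ties go to non-causality."""
    log_scores: dict[str, float] = {}
    for cls in CLASSES:
        score = math.log(model.prior(cls))
        for key in sorted(_freeze(k) for k in features.islp_matches):
            p = model.feature_prob("islp", key, cls)
            if p is not None:
                score += math.log(p)
        for key in sorted(_freeze(list(k)) for k in features.word_pairs):
            p = model.feature_prob("wp", key, cls)
            if p is not None:
                score += math.log(p)
        log_scores[cls] = score
    if log_scores["causality"] > log_scores["non-causality"]:
        label = "causality"
    else:
        label = "non-causality"
    return Prediction(label=label, log_scores=log_scores)


def save_model(model: CausalityModel, path: str | Path) -> None:
    """Persist a model as versioned JSON."""
    obj = {
        "format": "causepattern-model",
        "version": model.version,
        "smoothing": model.smoothing,
        "class_counts": model.class_counts,
        "islp_counts": model.islp_counts,
        "wp_counts": model.wp_counts,
        "islp_vocab": model.islp_vocab,
        "wp_vocab": model.wp_vocab,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def load_model(path: str | Path) -> CausalityModel:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    if obj.get("format") != "causepattern-model":
        raise ValueError(f"{path} is not a causepattern model file")
    return CausalityModel(
        class_counts=obj["class_counts"],
        islp_counts=obj["islp_counts"],
        wp_counts=obj["wp_counts"],
        islp_vocab=obj["islp_vocab"],
        wp_vocab=obj["wp_vocab"],
        smoothing=obj["smoothing"],
        version=obj["version"],
    )
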