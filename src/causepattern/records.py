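"""Core domain types shared across the package.

The unit of analysis is a *sentence pair*: a cause text span and an effect
text span, obtained either by splitting an explicit causality sentence on a
discourse connective, or given directly as two adjacent sentences.  Tokens
carry a coarse part-of-speech category because pattern generation considers
only nouns and verbs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Token",
    "Span",
    "SentencePairRecord",
    "ConnectiveLexicon",
    "COARSE_POS",
    "normalize_pos",
]

#: Coarse part-of-speech categories used throughout the pipeline.
COARSE_POS = ("noun", "verb", "other")

# Common fine-grained tag prefixes mapped onto the coarse categories.
# Covers Universal POS and Penn-style tags; anything unrecognized is "other".
_POS_MAP = {
    "noun": "noun",
    "n": "noun",
    "nn": "noun",
    "nns": "noun",
    "nnp": "noun",
    "nnps": "noun",
    "propn": "noun",
    "verb": "verb",
    "v": "verb",
    "vb": "verb",
    "vbd": "verb",
    "vbg": "verb",
    "vbn": "verb",
    "vbp": "verb",
    "vbz": "verb",
    "other": "other",
}


def normalize_pos(tag: str) -> str:
    """Map a POS tag to one of the coarse categories ``noun``/``verb``/``other``."""
    t = tag.strip().lower()
    if t in _POS_MAP:
        return _POS_MAP[t]
    if t.startswith("n"):
        return "noun"
    if t.startswith("v"):
        return "verb"
    return "other"


@dataclass(frozen=True)
class Token:
    """A single token: surface form plus coarse POS category."""

    surface: str
    pos: str = "other"

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("Token surface must be non-empty")
        if self.pos not in COARSE_POS:
            object.__setattr__(self, "pos", normalize_pos(self.pos))


@dataclass(frozen=True)
class Span:
    """An ordered token sequence playing the cause or the effect role."""

    tokens: tuple[Token, ...]
    role: str  # "cause" | "effect"

    def __post_init__(self) -> None:
        if self.role not in ("cause", "effect"):
            raise ValueError(f"Span role must be 'cause' or 'effect', got {self.role!r}")
        object.__setattr__(self, "tokens", tuple(self.tokens))

    @property
    def surfaces(self) -> tuple[str, ...]:
        return tuple(t.surface for t in self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


LABELS = ("causality", "non-causality", "unlabeled")


@dataclass(frozen=True)
class SentencePairRecord:
    """A cause span + effect span with a causality label.

    This is the unit of training and prediction: the classifier decides
    whether the pair expresses an (implicit) cause-effect relation.
    """

    id: str
    cause: Span
    effect: Span
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.cause.role != "cause":
            raise ValueError("cause span must have role 'cause'")
        if self.effect.role != "effect":
            raise ValueError("effect span must have role 'effect'")


@dataclass
class ConnectiveLexicon:
    """Discourse connectives with the direction of the causal relation.

    ``directions`` maps a case-folded connective string (tokens joined by a
    single space; connectives may be multi-token) to either ``cause-first``
    (the text before the connective is the cause, e.g. "so") or
    ``effect-first`` (the cause follows the connective, e.g. "because").
    """

    directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for conn, direction in self.directions.items():
            if direction not in ("cause-first", "effect-first"):
                raise ValueError(
                    f"direction for {conn!r} must be 'cause-first' or 'effect-first'"
                )

    @property
    def connectives(self) -> set[str]:
        return set(self.directions)

    def add(self, connective: str, direction: str) -> None:
        key = " ".join(connective.casefold().split())
        if direction not in ("cause-first", "effect-first"):
            raise ValueError(f"bad direction {direction!r} for connective {connective!r}")
        self.directions[key] = direction

    def token_sequences(self) -> list[tuple[tuple[str, ...], str]]:
        """Connectives as token tuples, longest first (for greedy matching)."""
        seqs = [(tuple(c.split()), d) for c, d in self.directions.items()]
        seqs.sort(key=lambda cd: (-len(cd[0]), cd[0]))
        return seqs

    def __len__(self) -> int:
        return len(self.directions)
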