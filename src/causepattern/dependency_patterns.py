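"""Parse-derived intra-sentential patterns (word/head dependency pairs).

Instead of mining frequent word sets, intra-sentential patterns can be read
off a dependency parse: every (dependent, head) arc is a two-word pattern.
Parses are consumed, never produced — they arrive as standard 10-column
CoNLL-U, one sentence per block, keyed to corpus records through

    # sent_id = <record-id>/<cause|effect>

comments.  Function words are retained at extraction time (the parse example
"My boss cut my salary" yields (my, boss), (my, salary), (boss, cut),
(salary, cut)); downstream support/confidence filtering decides what
survives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .pattern_mining import IntraPattern, MiningConfig
from .records import normalize_pos

logger = logging.getLogger(__name__)

__all__ = [
    "ParsedToken",
    "ParsedSpan",
    "ParseFormatError",
    "load_conllu",
    "extract_dependency_pairs",
    "dependency_intra_patterns",
]


class ParseFormatError(ValueError):
    """A CoNLL-U file or parse tree violates the expected structure."""


@dataclass(frozen=True)
class ParsedToken:
    surface: str
    pos: str
    head: int  # 1-based index into the span; 0 = root
    deprel: str = "_"


@dataclass(frozen=True)
class ParsedSpan:
    """A dependency-parsed span: exactly one root, heads in range, acyclic."""

    sent_id: str  # "<record-id>/<cause|effect>"
    tokens: tuple[ParsedToken, ...]

    def __post_init__(self) -> None:
        n = len(self.tokens)
        roots = [i for i, t in enumerate(self.tokens) if t.head == 0]
        for i, t in enumerate(self.tokens):
            if not (0 <= t.head <= n):
                raise ParseFormatError(
                    f"sentence {self.sent_id!r}: head index {t.head} of token "
                    f"{i + 1} out of range (1..{n})"
                )
        if n and len(roots) != 1:
            raise ParseFormatError(
                f"sentence {self.sent_id!r}: expected exactly one root, found {len(roots)}"
            )
        # cycle check: walking head links from any token must reach the root
        for i in range(n):
            seen = set()
            j = i
            while self.tokens[j].head != 0:
                if j in seen:
                    raise ParseFormatError(f"sentence {self.sent_id!r}: cyclic parse")
                seen.add(j)
                j = self.tokens[j].head - 1

    @property
    def record_id(self) -> str:
        return self.sent_id.rsplit("/", 1)[0]

    @property
    def side(self) -> str:
        tail = self.sent_id.rsplit("/", 1)[-1]
        return tail if tail in ("cause", "effect") else ""


def load_conllu(path: str | Path) -> list[ParsedSpan]:
    """Read parsed spans from a 10-column CoNLL-U file.

    Multiword-token and empty-node lines (ids with ``-`` or ``.``) are
    skipped.  Each sentence must carry a ``# sent_id`` comment; structural
    errors name the offending sentence.
    """
    spans: list[ParsedSpan] = []
    sent_id = ""
    rows: list[ParsedToken] = []
    anon = 0

    def flush() -> None:
        nonlocal sent_id, rows, anon
        if rows:
            sid = sent_id
            if not sid:
                anon += 1
                sid = f"sentence-{anon}"
            spans.append(ParsedSpan(sent_id=sid, tokens=tuple(rows)))
        sent_id = ""
        rows = []

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.lower().startswith("sent_id"):
                    _, _, value = body.partition("=")
                    sent_id = value.strip()
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise ParseFormatError(
                    f"line {lineno}: expected 10 tab-separated columns, got {len(cols)}"
                )
            tok_id = cols[0]
            if "-" in tok_id or "." in tok_id:
                continue  # multiword-token range / empty node
            try:
                head = int(cols[6])
            except ValueError as exc:
                raise ParseFormatError(
                    f"line {lineno}: HEAD column {cols[6]!r} is not an integer"
                ) from exc
            rows.append(
                ParsedToken(
                    surface=cols[1], pos=normalize_pos(cols[3]), head=head, deprel=cols[7]
                )
            )
        flush()
    if not spans:
        logger.warning("CoNLL-U file %s contained no sentences", path)
    return spans


def extract_dependency_pairs(parsed: ParsedSpan) -> list[IntraPattern]:
    """One (dependent, head) two-word pattern per non-root token.

    Confidence is assigned later (by MI over the span collection), so the
    returned patterns carry confidence 0.  A span of n tokens yields exactly
    n - 1 pairs.
    """
    side = parsed.side or "cause"
    pairs: list[IntraPattern] = []
    for tok in parsed.tokens:
        if tok.head == 0:
            continue
        head_tok = parsed.tokens[tok.head - 1]
        pairs.append(
            IntraPattern(
                words=(tok.surface, head_tok.surface), side=side, confidence=0.0
            )
        )
    return pairs


def dependency_intra_patterns(
    parses: Sequence[ParsedSpan],
    spans: Sequence[Sequence[str]],
    config: MiningConfig,
    side: str,
) -> list[IntraPattern]:
    """Side-tagged intra patterns from parses, filtered like mined ones.

    Dependency pairs are deduplicated, their span-containment support is
    counted over ``spans`` (the same text spans used for mining), and the
    same minimum-support and MI-confidence rules are applied so the two
    intra-pattern methods feed the inter stage on equal footing.
    """
    from .pattern_mining import _apply_confidence_rule, _mi  # shared internals

    tsets = [frozenset(s) for s in spans]
    n = len(tsets)
    word_counts: dict[str, int] = {}
    for t in tsets:
        for w in t:
            word_counts[w] = word_counts.get(w, 0) + 1

    seen: dict[frozenset, tuple[str, str]] = {}
    for parse in parses:
        if parse.side and parse.side != side:
            continue
        for pat in extract_dependency_pairs(parse):
            words = (pat.words[0].casefold(), pat.words[1].casefold())
            if words[0] == words[1]:
                continue
            seen.setdefault(frozenset(words), words)

    scored: list[IntraPattern] = []
    for wset, words in seen.items():
        if any(word_counts.get(w, 0) == 0 for w in wset):
            continue
        supp = sum(1 for t in tsets if wset <= t)
        if supp < config.min_support:
            continue
        conf = _mi(supp, [word_counts[w] for w in wset], n)
        scored.append(IntraPattern(words=words, side=side, confidence=conf, support=supp))
    return _apply_confidence_rule(scored, config)
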