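"""Reading and writing sentence-pair corpora and connective lexicons.

Two serializations are supported:

* JSONL (primary): one record per line, fields ``id``, ``cause``, ``effect``,
  ``label``; spans are lists of ``[surface, pos]`` pairs.
* TSV: four columns ``id``, cause tokens, effect tokens, ``label``; tokens
  encoded as space-separated ``surface/POS`` items.

Also implements the splitting of explicit causality sentences into cause and
effect spans by removing the discourse connective, and the noun/verb content
filter applied before pattern mining.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

from .records import ConnectiveLexicon, Span, SentencePairRecord, Token, normalize_pos

logger = logging.getLogger(__name__)

__all__ = [
    "CorpusFormatError",
    "load_corpus",
    "save_corpus",
    "load_lexicon",
    "save_lexicon",
    "split_on_connective",
    "content_words",
]


class CorpusFormatError(ValueError):
    """A corpus or lexicon file violates the expected format."""


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("jsonl", "tsv"):
            raise ValueError(f"unknown corpus format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    return "tsv" if suffix in (".tsv", ".tab") else "jsonl"


def _tokens_from_json(obj: object, field: str, lineno: int) -> tuple[Token, ...]:
    if not isinstance(obj, list):
        raise CorpusFormatError(f"line {lineno}: field '{field}' must be a token list")
    toks = []
    for item in obj:
        if not (isinstance(item, (list, tuple)) and len(item) == 2):
            raise CorpusFormatError(
                f"line {lineno}: field '{field}' tokens must be [surface, pos] pairs"
            )
        surface, pos = item
        if not surface:
            raise CorpusFormatError(f"line {lineno}: empty token surface in '{field}'")
        toks.append(Token(str(surface), normalize_pos(str(pos))))
    return tuple(toks)


def _tokens_from_tsv(cell: str, field: str, lineno: int) -> tuple[Token, ...]:
    toks = []
    for item in cell.split():
        surface, sep, pos = item.rpartition("/")
        if not sep or not surface:
            raise CorpusFormatError(
                f"line {lineno}: token {item!r} in '{field}' is not 'surface/POS'"
            )
        toks.append(Token(surface, normalize_pos(pos)))
    return tuple(toks)


def load_corpus(path: str | Path, format: str | None = None) -> list[SentencePairRecord]:
    """Load sentence-pair records from a JSONL or TSV corpus file.

    Records are returned in file order.  Malformed lines raise
    :class:`CorpusFormatError` naming the offending line and field.
    """
    fmt = _infer_format(path, format)
    path = Path(path)
    records: list[SentencePairRecord] = []
    seen_ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if fmt == "jsonl":
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"line {lineno}: invalid JSON: {exc}") from exc
                if not isinstance(obj, dict):
                    raise CorpusFormatError(f"line {lineno}: record must be an object")
                for fieldname in ("id", "cause", "effect"):
                    if fieldname not in obj:
                        raise CorpusFormatError(
                            f"line {lineno}: missing mandatory field '{fieldname}'"
                        )
                rec = SentencePairRecord(
                    id=str(obj["id"]),
                    cause=Span(_tokens_from_json(obj["cause"], "cause", lineno), "cause"),
                    effect=Span(_tokens_from_json(obj["effect"], "effect", lineno), "effect"),
                    label=obj.get("label", "unlabeled"),
                )
            else:
                cols = line.split("\t")
                if len(cols) < 3:
                    raise CorpusFormatError(
                        f"line {lineno}: expected >=3 tab-separated columns, got {len(cols)}"
                    )
                rec_id, cause_cell, effect_cell = cols[0], cols[1], cols[2]
                label = cols[3] if len(cols) > 3 and cols[3] else "unlabeled"
                rec = SentencePairRecord(
                    id=rec_id,
                    cause=Span(_tokens_from_tsv(cause_cell, "cause", lineno), "cause"),
                    effect=Span(_tokens_from_tsv(effect_cell, "effect", lineno), "effect"),
                    label=label,
                )
            if rec.id in seen_ids:
                raise CorpusFormatError(f"line {lineno}: duplicate record id {rec.id!r}")
            seen_ids.add(rec.id)
            records.append(rec)
    if not records:
        logger.warning("corpus file %s contained no records", path)
    return records


def record_to_json(rec: SentencePairRecord) -> str:
    """Serialize one record as a canonical (byte-stable) JSON line."""
    obj = {
        "id": rec.id,
        "cause": [[t.surface, t.pos] for t in rec.cause.tokens],
        "effect": [[t.surface, t.pos] for t in rec.effect.tokens],
        "label": rec.label,
    }
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), ensure_ascii=False)


def save_corpus(
    records: Iterable[SentencePairRecord], path: str | Path, format: str | None = None
) -> None:
    """Write records to JSONL (canonical key order) or TSV."""
    fmt = _infer_format(path, format)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            if fmt == "jsonl":
                fh.write(record_to_json(rec) + "\n")
            else:
                cause = " ".join(f"{t.surface}/{t.pos}" for t in rec.cause.tokens)
                effect = " ".join(f"{t.surface}/{t.pos}" for t in rec.effect.tokens)
                fh.write(f"{rec.id}\t{cause}\t{effect}\t{rec.label}\n")


def load_lexicon(path: str | Path) -> ConnectiveLexicon:
    """Load a connective lexicon: one ``connective<TAB>direction`` per line.

    ``#`` starts a comment; connectives are case-folded; the direction says
    which side of the connective holds the cause span.
    """
    lex = ConnectiveLexicon()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusFormatError(
                    f"line {lineno}: expected 'connective<TAB>direction', got {line!r}"
                )
            try:
                lex.add(parts[0], parts[1].strip())
            except ValueError as exc:
                raise CorpusFormatError(f"line {lineno}: {exc}") from exc
    if len(lex) == 0:
        raise CorpusFormatError(f"lexicon file {path} contains no connectives")
    return lex


def save_lexicon(lex: ConnectiveLexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for conn in sorted(lex.directions):
            fh.write(f"{conn}\t{lex.directions[conn]}\n")


def _find_connective(
    surfaces: Sequence[str], lexicon: ConnectiveLexicon
) -> list[tuple[int, int, str]]:
    """All (start, end, direction) matches of lexicon connectives, left to right.

    Matching is case-folded and greedy: at each position the longest
    connective wins; matches never overlap.
    """
    folded = [s.casefold() for s in surfaces]
    seqs = lexicon.token_sequences()
    matches: list[tuple[int, int, str]] = []
    i = 0
    while i < len(folded):
        hit = None
        for seq, direction in seqs:
            if tuple(folded[i : i + len(seq)]) == seq:
                hit = (i, i + len(seq), direction)
                break
        if hit:
            matches.append(hit)
            i = hit[1]
        else:
            i += 1
    return matches


def split_on_connective(
    sentence_tokens: Sequence[Token],
    lexicon: ConnectiveLexicon,
    record_id: str = "",
    label: str = "causality",
) -> SentencePairRecord | None:
    """Split an explicit causality sentence on its discourse connective.

    Removes the connective and assigns the two remaining stretches to cause
    and effect according to the connective's direction (``cause-first``: the
    text before the connective is the cause; ``effect-first``: the cause
    follows the connective).  Returns ``None`` if no lexicon connective
    occurs, or if the split would leave an empty span (logged and skipped).
    With several connective occurrences the first is used (warning logged).
    """
    tokens = list(sentence_tokens)
    matches = _find_connective([t.surface for t in tokens], lexicon)
    if not matches:
        return None
    if len(matches) > 1:
        logger.warning(
            "sentence %r contains %d lexicon connectives; splitting on the first",
            record_id or "<unnamed>",
            len(matches),
        )
    start, end, direction = matches[0]
    before = tuple(tokens[:start])
    after = tuple(tokens[end:])
    if not before or not after:
        logger.warning(
            "connective at sentence edge leaves an empty span; skipping record %r",
            record_id or "<unnamed>",
        )
        return None
    if direction == "cause-first":
        cause_toks, effect_toks = before, after
    else:
        cause_toks, effect_toks = after, before
    return SentencePairRecord(
        id=record_id or "pair",
        cause=Span(cause_toks, "cause"),
        effect=Span(effect_toks, "effect"),
        label=label,
    )


def content_words(span: Span) -> list[str]:
    """Case-folded surfaces of the span's nouns and verbs, in order.

    Only nouns and verbs take part in language-pattern generation; all other
    tokens are dropped here.  Duplicates are retained; case is folded so
    that word identity (and hence support counting and feature matching) is
    case-insensitive.
    """
    return [t.surface.casefold() for t in span.tokens if t.pos in ("noun", "verb")]
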