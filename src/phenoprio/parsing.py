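"""Recover ordered gene lists from free-text ranker output.

Model responses wrap the ranking in prose: numbered lines, inline
numbered lists, bullets, or a comma-separated list after a
"Ranked List:" marker, frequently interleaved with explanation
sentences.  This module extracts the ranking and quantifies the three
list-level hallucination modes: *missing* input genes, *extra*
non-input symbols, and duplicates.

All pathologies are data, not exceptions — a response ranking only some
of the input genes is a valid parse with a non-empty ``missing`` set; a
response with no recoverable list at all is marked ``failed``.

Symbol matching is case-insensitive exact after normalization, with an
optional alias table for synonym symbols.  No fuzzy matching is
performed: awarding credit for a near-miss symbol would fake accuracy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = ["ParsedRanking", "normalize_symbol", "parse_response", "read_alias_table"]


@dataclass
class ParsedRanking:
    case_id: Optional[str] = None
    ranked_genes: list[str] = field(default_factory=list)
    missing: set[str] = field(default_factory=set)
    extra: set[str] = field(default_factory=set)
    duplicates_collapsed: int = 0
    failed: bool = False


_PAREN_RE = re.compile(r"\([^)]*\)")
_SEPARATOR_RE = re.compile(r":|\s[-–—]\s")
_EDGE_PUNCT = " \t*_`'\".,;:!-–—()[]{}"

# one numbered item; the lookahead stops inline items at the next number
_ITEM_RE = re.compile(r"(\d+)[.)]\s*([^\n]*?)(?=\s+\d+[.)]\s|\n|$)")
_BULLET_RE = re.compile(r"^\s*[-*•]\s+(.+)$", re.MULTILINE)
_MARKER_RE = re.compile(r"ranked\s+list\s*:?", re.IGNORECASE)


def normalize_symbol(text: str) -> str:
    """Normalize one candidate token to a bare uppercase gene symbol.

    Drops parenthetical asides, truncates at the first explanation
    separator (colon, or a dash set off by spaces), strips markdown
    emphasis and surrounding punctuation, keeps the first whitespace
    token, and uppercases.
    """
    s = _PAREN_RE.sub(" ", text)
    s = _SEPARATOR_RE.split(s, maxsplit=1)[0]
    s = s.strip(_EDGE_PUNCT)
    if not s:
        return ""
    return s.split()[0].strip(_EDGE_PUNCT).upper()


def _numbered_runs(text: str) -> list[tuple[int, list[str]]]:
    """Group numbered items into runs; a new run starts at item number 1."""
    runs: list[tuple[int, list[str]]] = []
    current: Optional[list[str]] = None
    for match in _ITEM_RE.finditer(text):
        number, body = int(match.group(1)), match.group(2)
        if current is None or number == 1:
            current = []
            runs.append((match.start(), current))
        current.append(body)
    return runs


def _pick_run(runs: list[tuple[int, list[str]]], marker_end: Optional[int]):
    if not runs:
        return None
    if marker_end is not None:
        after = [r for r in runs if r[0] >= marker_end]
        pool = after or runs
        return min(pool, key=lambda r: abs(r[0] - marker_end))[1]
    return max(runs, key=lambda r: len(r[1]))[1]


def _candidate_tokens(raw_text: str) -> Optional[list[str]]:
    marker = None
    for m in _MARKER_RE.finditer(raw_text):
        marker = m  # keep the last marker: models sometimes restate it
    marker_end = marker.end() if marker else None

    runs = _numbered_runs(raw_text)
    chosen = _pick_run(runs, marker_end)
    if chosen:
        return chosen

    bullets = _BULLET_RE.findall(raw_text)
    if bullets:
        return bullets

    if marker is not None:
        tail = raw_text[marker.end():].split("\n", 1)[0]
        parts = [p for p in tail.split(",") if p.strip()]
        if len(parts) >= 2:
            return parts
    return None


def parse_response(
    raw_text: str,
    input_genes: Iterable[str],
    alias_table: Optional[Mapping[str, str]] = None,
    case_id: Optional[str] = None,
) -> ParsedRanking:
    """Extract the ranked gene list from a raw response.

    When several numbered lists appear, the one nearest after a
    "Ranked List" marker wins; without a marker, the longest list is
    taken.  Candidate tokens are normalized, optionally alias-mapped, and
    de-duplicated keeping the first occurrence.  Tokens matching no input
    gene are reported as ``extra``; input genes never seen as
    ``missing``.
    """
    inputs = {g.upper() for g in input_genes}
    if not inputs:
        raise ValueError("input_genes must be non-empty")
    aliases = (
        {k.upper(): v.upper() for k, v in alias_table.items()} if alias_table else {}
    )

    tokens = _candidate_tokens(raw_text)
    if tokens is None:
        return ParsedRanking(case_id=case_id, missing=set(inputs), failed=True)

    ranked: list[str] = []
    extra: set[str] = set()
    seen: set[str] = set()
    duplicates = 0
    for token in tokens:
        symbol = normalize_symbol(token)
        if not symbol:
            continue
        symbol = aliases.get(symbol, symbol)
        if symbol in seen:
            duplicates += 1
            continue
        seen.add(symbol)
        if symbol in inputs:
            ranked.append(symbol)
        else:
            extra.add(symbol)

    return ParsedRanking(
        case_id=case_id,
        ranked_genes=ranked,
        missing=inputs - set(ranked),
        extra=extra,
        duplicates_collapsed=duplicates,
        failed=False,
    )


def read_alias_table(path) -> dict[str, str]:
    """Load a two-column TSV (alias, canonical) into a mapping."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            alias, canonical = line.split("\t")[:2]
            table[alias] = canonical
    return table
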