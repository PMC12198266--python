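"""PROSITE-style signature parsing and scanning.

The grammar covers the subset used by protein-family signatures: elements
separated by ``-``; an element is a residue literal, ``x`` (any residue),
``[SET]`` (alternatives) or ``{SET}`` (exclusions), optionally suffixed with
``(n)`` (fixed repeat) or ``(n,m)`` (range repeat).  ``<`` / ``>`` terminal
anchors are honoured.  Matching is exact (no mismatches); for range repeats
the shortest assignment per start is reported (non-greedy semantics), and
overlapping matches at distinct starts are all reported.

``brute_force_scan`` enumerates repeat-width assignments exhaustively and
serves as an independent oracle for ``scan``.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from aaokit.records import AMINO_ACIDS, AA_SET, ProteinRecord

#: sentinel for elements matching any residue (including sequence 'X')
ANY = frozenset(AMINO_ACIDS + "X")


class PrositeSyntaxError(ValueError):
    """Raised on malformed signature text; names the offending element index."""

    def __init__(self, message: str, element_index: int | None = None):
        if element_index is not None:
            message = f"element {element_index}: {message}"
        super().__init__(message)
        self.element_index = element_index


@dataclass(frozen=True)
class PatternElement:
    allowed: frozenset[str]
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if not self.allowed:
            raise ValueError("empty allowed set")
        if self.min_repeat < 1 or self.max_repeat < self.min_repeat:
            raise ValueError("invalid repeat bounds")


@dataclass(frozen=True)
class PrositePattern:
    """Parsed signature: an ordered list of residue-set elements with repeats."""

    pattern_id: str
    elements: tuple[PatternElement, ...]
    source_text: str
    anchored_start: bool = False
    anchored_end: bool = False

    @property
    def min_span(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def max_span(self) -> int:
        return sum(e.max_repeat for e in self.elements)


@dataclass(frozen=True)
class MotifHit:
    """A located signature instance; 0-based half-open coordinates."""

    pattern_id: str
    seq_id: str
    start: int
    end: int
    matched_text: str


_REPEAT_RE = re.compile(r"\((\d+)(?:,(\d+))?\)$")


def _parse_element(token: str, index: int) -> PatternElement:
    m = _REPEAT_RE.search(token)
    min_rep = max_rep = 1
    if m:
        min_rep = int(m.group(1))
        max_rep = int(m.group(2)) if m.group(2) else min_rep
        if min_rep < 1 or max_rep < min_rep:
            raise PrositeSyntaxError(f"bad repeat in {token!r}", index)
        token = token[: m.start()]
    elif "(" in token or ")" in token:
        raise PrositeSyntaxError(f"malformed repeat in {token!r}", index)
    if token == "x":
        allowed = ANY
    elif token.startswith("[") or token.startswith("{"):
        close = "]" if token[0] == "[" else "}"
        if not token.endswith(close) or len(token) < 3:
            raise PrositeSyntaxError(f"unbalanced bracket in {token!r}", index)
        letters = token[1:-1]
        bad = set(letters) - AA_SET
        if bad:
            raise PrositeSyntaxError(f"non-residue letters {sorted(bad)} in {token!r}", index)
        if token[0] == "[":
            allowed = frozenset(letters)
        else:  # exclusion set: any residue except those listed; 'X' never matches
            allowed = frozenset(AA_SET - set(letters))
        if not allowed:
            raise PrositeSyntaxError(f"empty residue set in {token!r}", index)
    elif len(token) == 1 and token in AA_SET:
        allowed = frozenset(token)
    else:
        raise PrositeSyntaxError(f"unrecognised element {token!r}", index)
    return PatternElement(allowed, min_rep, max_rep)


def parse_prosite(text: str, pattern_id: str = "") -> PrositePattern:
    """Parse a PROSITE signature string into an executable pattern."""
    source = text
    text = text.strip().rstrip(".")
    if not text:
        raise PrositeSyntaxError("empty pattern")
    anchored_start = text.startswith("<")
    anchored_end = text.endswith(">")
    text = text.lstrip("<").rstrip(">")
    tokens = text.split("-")
    elements = tuple(_parse_element(tok, i) for i, tok in enumerate(tokens))
    if not elements:
        raise PrositeSyntaxError("pattern has no elements")
    return PrositePattern(
        pattern_id or source, elements, source, anchored_start, anchored_end
    )


def _element_regex(e: PatternElement) -> str:
    cls = "[" + "".join(sorted(e.allowed)) + "]"
    if e.min_repeat == e.max_repeat:
        rep = "" if e.min_repeat == 1 else f"{{{e.min_repeat}}}"
    else:
        # non-greedy: shortest assignment per start
        rep = f"{{{e.min_repeat},{e.max_repeat}}}?"
    return cls + rep


def compile_pattern(pattern: PrositePattern) -> re.Pattern[str]:
    body = "".join(_element_regex(e) for e in pattern.elements)
    if pattern.anchored_end:
        body += r"\Z"
    return re.compile(body)


def scan(
    pattern: PrositePattern,
    record: ProteinRecord,
    window: tuple[int, int] | None = None,
) -> list[MotifHit]:
    """Report every match whose start lies in *window* (whole sequence if None).

    Overlapping matches at distinct starts are all reported; at a given start
    a range-repeat pattern reports its shortest match.
    """
    seq = record.sequence
    lo, hi = window if window is not None else (0, len(seq))
    lo, hi = max(lo, 0), min(hi, len(seq))
    rx = compile_pattern(pattern)
    starts: Iterable[int]
    if pattern.anchored_start:
        starts = [0] if lo == 0 and hi > 0 else []
    else:
        starts = range(lo, hi)
    hits = []
    for s in starts:
        m = rx.match(seq, s)
        if m:
            hits.append(MotifHit(pattern.pattern_id, record.id, s, m.end(), seq[s : m.end()]))
    return hits


def brute_force_scan(
    pattern: PrositePattern,
    record: ProteinRecord,
    window: tuple[int, int] | None = None,
) -> list[MotifHit]:
    """Exhaustive oracle: try every start and every repeat-width assignment.

    Width assignments are explored in ascending lexicographic order so the
    first success per start is the non-greedy (shortest-earliest) match,
    matching :func:`scan`'s contract.
    """
    seq = record.sequence
    lo, hi = window if window is not None else (0, len(seq))
    lo, hi = max(lo, 0), min(hi, len(seq))
    starts: Iterable[int]
    if pattern.anchored_start:
        starts = [0] if lo == 0 and hi > 0 else []
    else:
        starts = range(lo, hi)
    hits = []
    ranges = [range(e.min_repeat, e.max_repeat + 1) for e in pattern.elements]
    for s in starts:
        for widths in itertools.product(*ranges):
            pos = s
            ok = True
            for e, w in zip(pattern.elements, widths):
                chunk = seq[pos : pos + w]
                if len(chunk) < w or any(c not in e.allowed for c in chunk):
                    ok = False
                    break
                pos += w
            if ok and (not pattern.anchored_end or pos == len(seq)):
                hits.append(MotifHit(pattern.pattern_id, record.id, s, pos, seq[s:pos]))
                break
    return hits


def load_signatures(path: str | Path) -> dict[str, PrositePattern]:
    """Load signatures from a plain-text file, one ``id<TAB>pattern`` per line."""
    patterns: dict[str, PrositePattern] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            pid, text = line.split("\t", 1)
        except ValueError as exc:
            raise PrositeSyntaxError(f"line {lineno}: expected 'id<TAB>pattern'") from exc
        patterns[pid] = parse_prosite(text.strip(), pid)
    return patterns


def write_hits_tsv(hits: Sequence[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based half-open\n")
        fh.write("pattern_id\tseq_id\tstart\tend\tmatched_text\n")
        for h in hits:
            fh.write(f"{h.pattern_id}\t{h.seq_id}\t{h.start}\t{h.end}\t{h.matched_text}\n")
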