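"""Within-admission duplicate text removal.

Concatenated admission documents carry replicated sentences, paragraphs and
list items (copy-forwarded boilerplate).  Replicates distort term statistics
and slow manual review, so before vectorization each admission document is
segmented into units and only the first occurrence of each unit is kept.

Segmentation has to cope with clinical-note conventions: sentences may end at
a period/question mark *or* at a bare newline, numbered or bulleted list items
are one unit each, and a period inside a decimal ("1.23") or a known
abbreviation ("dr.") does not end a sentence.

Duplicate detection is exact-match on a normalized key (lowercased, whitespace
collapsed) and is applied within one admission document only, never across
admissions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, List, Sequence

#: words whose trailing period does not end a sentence
ABBREVIATIONS = {
    "dr.", "mr.", "mrs.", "ms.", "st.", "jr.", "sr.", "vs.", "etc.",
    "e.g.", "i.e.", "approx.", "no.", "pt.", "prn.",
}

#: a line that is a numbered/bulleted list item is a single unit
_LIST_ITEM_RE = re.compile(r"^\s*(\d+[.)]|[-*•])\s+\S")

#: sentence terminator: '.' or '?' followed by at least one whitespace char
_SENT_END_RE = re.compile(r"[.?](\s+)")

_MARK_OPEN = "[[DUPLICATE]]"
_MARK_CLOSE = "[[/DUPLICATE]]"


@dataclass(frozen=True)
class TextUnit:
    """One segmentation unit (sentence / list item) of a document.

    ``raw`` is the exact source span including its trailing separator
    whitespace, so concatenating the ``raw`` spans of all units in
    ``position`` order reconstructs the pre-dedup document.
    """

    raw: str
    normalized_key: str
    position: int


def normalize_key(text: str) -> str:
    """Canonical form used for duplicate matching: lowercase, collapse whitespace."""
    return " ".join(text.lower().split())


def _split_line(line: str) -> List[str]:
    """Split one newline-terminated span into sentence spans.

    The trailing inter-sentence whitespace stays attached to the earlier
    span so the spans concatenate back to ``line`` exactly.
    """
    if _LIST_ITEM_RE.match(line):
        return [line]
    spans: List[str] = []
    start = 0
    for m in _SENT_END_RE.finditer(line):
        end_char = m.start()  # index of '.' or '?'
        if line[end_char] == ".":
            # decimal guard is implicit ('.' must be followed by whitespace);
            # abbreviation guard needs the word ending at this period
            word = re.search(r"(\S+)$", line[start : end_char + 1])
            if word and word.group(1).lower() in ABBREVIATIONS:
                continue
        spans.append(line[start : m.end()])
        start = m.end()
    if start < len(line):
        spans.append(line[start:])
    return spans


def segment_units(text: str) -> List[TextUnit]:
    """Segment a document into sentence / list-item units.

    Splits at sentence-final periods/question marks and at newline
    boundaries; numbered and bulleted list items are single units; decimal
    points and known abbreviations do not split.  Whitespace-only spans are
    merged into the neighbouring unit's ``raw`` (never returned as units), so
    reconstruction from raw spans is lossless.
    """
    if not text:
        return []
    # keep the newline attached to the line it terminates
    lines = re.split(r"(?<=\n)", text)
    spans: List[str] = []
    for line in lines:
        if not line:
            continue
        spans.extend(_split_line(line))

    units: List[TextUnit] = []
    pending_ws = ""  # whitespace-only spans waiting for a home
    for span in spans:
        key = normalize_key(span)
        if not key:
            if units:
                last = units[-1]
                units[-1] = TextUnit(last.raw + span, last.normalized_key, last.position)
            else:
                pending_ws += span
            continue
        units.append(TextUnit(pending_ws + span, key, len(units)))
        pending_ws = ""
    return units


def remove_duplicates(units: Sequence[TextUnit], mode: str = "remove") -> str:
    """Keep the first occurrence of each normalized key; drop or mark the rest.

    mode="remove" deletes later occurrences; mode="mark" wraps them in
    visible ``[[DUPLICATE]]`` markers for audit output.  Order is preserved.

    Removing a line-final unit keeps its line break, so the following unit
    (e.g. a numbered list item) stays at its line start and the output
    re-segments to the same remaining units.
    """
    if mode not in ("remove", "mark"):
        raise ValueError(f"mode must be 'remove' or 'mark', got {mode!r}")
    seen: set = set()
    pieces: List[str] = []
    for unit in units:
        if unit.normalized_key not in seen:
            seen.add(unit.normalized_key)
            pieces.append(unit.raw)
        elif mode == "mark":
            body = unit.raw.rstrip()
            trailer = unit.raw[len(body):]
            pieces.append(f"{_MARK_OPEN}{body}{_MARK_CLOSE}{trailer}")
        elif unit.raw.endswith("\n") and pieces and not pieces[-1].endswith("\n"):
            pieces.append("\n")
    return "".join(pieces)


def dedup_document(text: str, mode: str = "remove") -> str:
    """Segment ``text`` and remove (or mark) replicate units."""
    return remove_duplicates(segment_units(text), mode=mode)


def dedup_documents(texts: Iterable[str], mode: str = "remove") -> List[str]:
    """Apply :func:`dedup_document` per document (duplicates are never shared
    across admissions)."""
    return [dedup_document(t, mode=mode) for t in texts]
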