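"""Language-agnostic text normalization, sentence splitting, and tokenization.

Community messages are short and noisy: inconsistent casing, erratic
whitespace, and misspellings are the dominant error sources for downstream
dictionary matching.  All matching therefore happens on *normalized* text
(Unicode casefold, whitespace collapsed), with an offset map that projects
normalized spans back onto the raw text.

Morphological analysis is deliberately not built in.  ``Normalizer`` is a
hook: any callable with the same signature (text -> (normalized, offset_map))
can replace :func:`normalize_text`, so a morphological analyzer or spacing
corrector can be plugged in without touching downstream modules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Sequence

__all__ = [
    "Token",
    "Sentence",
    "Normalizer",
    "normalize_text",
    "project_span",
    "split_sentences",
    "tokenize",
]

# Maximal runs of letters/digits under Unicode word rules (no underscore).
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)
_SENT_DELIM = set(".!?\n")


@dataclass(frozen=True)
class Token:
    """A token with 0-based half-open character offsets into its source text."""

    text: str
    start: int
    end: int


@dataclass(frozen=True)
class Sentence:
    """A sentence with its 0-based half-open span in the source text."""

    text: str
    start: int
    end: int


#: Signature of a pluggable normalizer: text -> (normalized text, offset map).
Normalizer = Callable[[str], tuple[str, list[int]]]


def normalize_text(text: str) -> tuple[str, list[int]]:
    """Casefold and collapse whitespace, keeping a normalized->raw offset map.

    Returns ``(normalized, offsets)`` where ``offsets[i]`` is the index in
    ``text`` of the raw character that produced ``normalized[i]``.  A space in
    the normalized text maps to the first character of the whitespace run it
    replaced.  ``offsets`` has length ``len(normalized) + 1``; the final entry
    is the raw end position, so spans can be projected with
    :func:`project_span`.

    Casefolding may expand a character (e.g. ``ß`` -> ``ss``); all expanded
    characters map back to the single raw character.
    """
    out: list[str] = []
    offsets: list[int] = []
    pending_space_at: int | None = None
    for i, ch in enumerate(text):
        if ch.isspace():
            if pending_space_at is None:
                pending_space_at = i
            continue
        if pending_space_at is not None:
            if out:  # no leading space
                out.append(" ")
                offsets.append(pending_space_at)
            pending_space_at = None
        for folded in ch.casefold():
            out.append(folded)
            offsets.append(i)
    offsets.append(len(text))
    return "".join(out), offsets


def project_span(offsets: Sequence[int], start: int, end: int) -> tuple[int, int]:
    """Project a normalized-text span back to a raw-text span.

    ``offsets`` is the map returned by :func:`normalize_text`.  The raw span
    covers every raw character that contributed to the normalized span.
    """
    if not 0 <= start <= end <= len(offsets) - 1:
        raise ValueError(f"span ({start}, {end}) out of bounds")
    if start == end:
        pos = offsets[start]
        return pos, pos
    # normalized[end-1] came from the single raw character at offsets[end-1]
    # (casefold expansion maps several normalized chars to one raw char), so
    # the raw span ends right after it
    return offsets[start], offsets[end - 1] + 1


def split_sentences(text: str) -> list[Sentence]:
    """Split on ``.``, ``!``, ``?`` and newline, delimiter kept with its sentence.

    Runs of delimiters stay attached to the preceding sentence ("Wow!!" is one
    sentence).  Whitespace-only segments are dropped.  No abbreviation
    handling: community messages are short and rarely contain formal prose.
    """
    sentences: list[Sentence] = []
    start = 0
    i = 0
    n = len(text)
    while i < n:
        if text[i] in _SENT_DELIM:
            while i < n and text[i] in _SENT_DELIM:
                i += 1
            _append_sentence(sentences, text, start, i)
            start = i
        else:
            i += 1
    _append_sentence(sentences, text, start, n)
    return sentences


def _append_sentence(acc: list[Sentence], text: str, start: int, end: int) -> None:
    seg = text[start:end]
    stripped = seg.strip()
    if not stripped or all(c in _SENT_DELIM or c.isspace() for c in stripped):
        return
    lead = len(seg) - len(seg.lstrip())
    trail = len(seg) - len(seg.rstrip())
    acc.append(Sentence(seg.strip(), start + lead, end - trail))


def tokenize(text: str) -> list[Token]:
    """Tokens are maximal runs of letters/digits; offsets 0-based half-open."""
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
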