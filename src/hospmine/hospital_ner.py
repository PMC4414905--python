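"""Hospital mention extraction and stepwise canonical-name normalization.

Users write hospital names as acronyms, abbreviations and misspellings.  A
candidate surface form is resolved against the hospital dictionary by a
stepwise procedure:

1. **exact** — equality with a canonical name;
2. **alias** — equality with any listed alias;
3. **fuzzy** — minimal Levenshtein edit distance to any alias, accepted only
   when the distance is at most ``max(1, floor(max_rel_distance * len(alias)))``.

The first step that succeeds wins and is reported with the match.  Fuzzy ties
are broken by smallest distance, then same-region preference (when the
message's region is known), then longest alias, then lexicographically
smallest canonical id.  A candidate whose minimal-distance set still spans
two or more distinct hospitals after the region preference is flagged
*ambiguous*; the message filter drops messages carrying any ambiguous
candidate, since a reader cannot tell which hospital is meant.

Candidate spans are token n-grams (hospital names are multiword; scanning all
substrings would be quadratic for no benefit).  All matching happens on
normalized text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import edlib

from .lexicons import HospitalEntry, HospitalLexicon
from .corpus import Message
from .preprocess import normalize_text, tokenize

__all__ = [
    "NerConfig",
    "HospitalMention",
    "MatchResult",
    "edit_distance",
    "match_hospital",
    "extract_hospital_mentions",
    "filter_messages",
]


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance (insert/delete/substitute); symmetric."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


@dataclass(frozen=True)
class NerConfig:
    """Tunables for hospital-name matching.

    ``max_rel_distance`` is the fuzzy-step tolerance as a fraction of the
    alias length (every alias tolerates at least one edit); ``max_ngram`` is
    the longest candidate span in tokens.
    """

    max_rel_distance: float = 0.25
    max_ngram: int = 5


def fuzzy_threshold(alias: str, max_rel_distance: float) -> int:
    """Maximum accepted edit distance for an alias: max(1, floor(rel * len))."""
    return max(1, math.floor(max_rel_distance * len(alias)))


@dataclass(frozen=True)
class MatchResult:
    """Outcome of resolving one candidate surface against the dictionary."""

    canonical_id: str
    match_step: str  # exact | alias | fuzzy
    distance: int
    ambiguous: bool = False


@dataclass(frozen=True)
class HospitalMention:
    """One resolved hospital mention in a message (span in normalized text)."""

    message_id: str
    surface: str
    span: tuple[int, int]
    canonical_id: str
    match_step: str
    distance: int
    ambiguous: bool = False


def _tie_break(
    candidates: list[tuple[int, str, HospitalEntry]], region: str | None
) -> tuple[MatchResult, list[tuple[int, str, HospitalEntry]]]:
    """Pick a winner among (distance, alias, entry) fuzzy candidates.

    Order: smallest distance; same-region entries first when ``region`` is
    known; longest alias; smallest canonical_id.  Returns the result plus the
    minimal-distance pool used for the ambiguity decision.
    """
    dmin = min(c[0] for c in candidates)
    pool = [c for c in candidates if c[0] == dmin]
    if region is not None:
        regional = [c for c in pool if c[2].region == region]
        if regional:
            pool = regional
    pool.sort(key=lambda c: (-len(c[1]), c[2].canonical_id))
    ids = {c[2].canonical_id for c in pool}
    winner = pool[0]
    return (
        MatchResult(winner[2].canonical_id, "fuzzy", dmin, ambiguous=len(ids) > 1),
        pool,
    )


def match_hospital(
    candidate: str,
    lexicon: HospitalLexicon,
    region: str | None = None,
    max_rel_distance: float = 0.25,
) -> MatchResult | None:
    """Resolve a normalized candidate via the exact -> alias -> fuzzy steps.

    Returns ``None`` when no step succeeds (no-match is a value, not an
    error).  The fuzzy step scans every alias and accepts only within the
    per-alias threshold; see :func:`fuzzy_threshold`.
    """
    exact = lexicon.lookup_canonical(candidate)
    if exact:
        entry = _prefer_region(exact, region)
        return MatchResult(entry.canonical_id, "exact", 0,
                           ambiguous=len({e.canonical_id for e in exact}) > 1
                           and not _region_unique(exact, region))
    alias_hits = lexicon.lookup_alias(candidate)
    if alias_hits:
        entry = _prefer_region(alias_hits, region)
        return MatchResult(entry.canonical_id, "alias", 0,
                           ambiguous=len({e.canonical_id for e in alias_hits}) > 1
                           and not _region_unique(alias_hits, region))
    candidates: list[tuple[int, str, HospitalEntry]] = []
    for alias, entry in lexicon.alias_pairs():
        limit = fuzzy_threshold(alias, max_rel_distance)
        if abs(len(alias) - len(candidate)) > limit:
            continue  # length difference alone already exceeds the budget
        d = edit_distance(candidate, alias)
        if d <= limit:
            candidates.append((d, alias, entry))
    if not candidates:
        return None
    result, _ = _tie_break(candidates, region)
    return result


def _prefer_region(entries: list[HospitalEntry], region: str | None) -> HospitalEntry:
    pool = entries
    if region is not None:
        regional = [e for e in entries if e.region == region]
        if regional:
            pool = regional
    return min(pool, key=lambda e: e.canonical_id)


def _region_unique(entries: list[HospitalEntry], region: str | None) -> bool:
    if region is None:
        return False
    regional = {e.canonical_id for e in entries if e.region == region}
    return len(regional) == 1


def extract_hospital_mentions(
    message: Message,
    lexicon: HospitalLexicon,
    config: NerConfig = NerConfig(),
    use_region: bool = True,
) -> list[HospitalMention]:
    """Scan a message for hospital mentions; longest match wins on overlap.

    The normalized message text is tokenized and every token n-gram up to
    ``config.max_ngram`` is resolved with :func:`match_hospital`.  Overlapping
    matches are reduced greedily: longer spans first, then earlier spans,
    then cheaper (smaller-distance) matches.  Spans are 0-based half-open
    offsets into the *normalized* text.
    """
    normalized, _ = normalize_text(message.raw_text)
    tokens = tokenize(normalized)
    region = message.region if use_region else None
    raw_matches: list[tuple[tuple[int, int], str, MatchResult]] = []
    for i in range(len(tokens)):
        for n in range(1, config.max_ngram + 1):
            j = i + n
            if j > len(tokens):
                break
            start, end = tokens[i].start, tokens[j - 1].end
            surface = normalized[start:end]
            result = match_hospital(
                surface, lexicon, region=region, max_rel_distance=config.max_rel_distance
            )
            if result is not None:
                raw_matches.append(((start, end), surface, result))
    # certain (distance-0) matches outrank fuzzy guesses, so a loose fuzzy
    # superstring cannot absorb a verbatim alias plus a neighbor token;
    # within each class: longest span first, then leftmost, then cheapest
    raw_matches.sort(
        key=lambda m: (
            m[2].distance > 0,
            -(m[0][1] - m[0][0]),
            m[0][0],
            m[2].distance,
        )
    )
    chosen: list[tuple[tuple[int, int], str, MatchResult]] = []
    occupied: list[tuple[int, int]] = []
    for span, surface, result in raw_matches:
        if any(span[0] < e and s < span[1] for s, e in occupied):
            continue
        occupied.append(span)
        chosen.append((span, surface, result))
    chosen.sort(key=lambda m: m[0])
    return [
        HospitalMention(
            message_id=message.message_id,
            surface=surface,
            span=span,
            canonical_id=result.canonical_id,
            match_step=result.match_step,
            distance=result.distance,
            ambiguous=result.ambiguous,
        )
        for span, surface, result in chosen
    ]


def filter_messages(
    messages: Iterable[Message],
    mentions: Iterable[HospitalMention],
) -> list[Message]:
    """Keep messages that clearly mention a hospital.

    A message is retained iff it has at least one resolved mention and none
    of its candidate spans is ambiguous (tied between distinct hospitals at
    the minimal fuzzy distance).  Order is preserved.
    """
    by_message: dict[str, list[HospitalMention]] = {}
    for m in mentions:
        by_message.setdefault(m.message_id, []).append(m)
    retained = []
    for msg in messages:
        ms = by_message.get(msg.message_id, [])
        if ms and not any(m.ambiguous for m in ms):
            retained.append(msg)
    return retained
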