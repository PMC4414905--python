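"""Detection of the six service-quality factors by dictionary matching.

Keyword matching runs per sentence on normalized text.  Matches must align
with token boundaries, multiword keywords are supported, and overlaps are
resolved longest-match-first ("waiting time" beats "waiting").  Equivalent
surface forms resolve to their owning lexicon entry, so counts aggregate on
the canonical keyword.

No stemming or compound-noun decomposition is attempted: the detector
mirrors a plain keyword-list mechanism, and its known failure modes (unsplit
compounds, homonyms) are accepted as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import Message
from .lexicons import FactorKeywordEntry, FactorLexicon
from .preprocess import normalize_text, split_sentences, tokenize

__all__ = [
    "FactorMention",
    "match_keywords",
    "detect_factor_mentions",
    "count_factors",
    "sentence_texts",
]

GROUP_KEYS = ("region", "year", "month", "factor", "subcategory", "canonical_id")


@dataclass(frozen=True)
class FactorMention:
    """One detected quality-factor keyword occurrence.

    ``span`` is 0-based half-open in the normalized sentence text;
    ``matched_keyword`` is the owning entry's canonical keyword (equivalents
    resolve to it); ``surface`` is the text actually matched.
    """

    message_id: str
    sentence_index: int
    span: tuple[int, int]
    surface: str
    matched_keyword: str
    factor: str
    subcategory: str


def match_keywords(
    normalized_text: str,
    surface_map: Mapping[str, object],
    max_tokens: int | None = None,
) -> list[tuple[tuple[int, int], str, object]]:
    """Token-boundary keyword matching, longest-match-first, non-overlapping.

    ``surface_map`` maps normalized surfaces to arbitrary payloads (a factor
    entry, a sentiment polarity, ...).  Returns ``(span, surface, payload)``
    triples in span order.  Shared by factor detection and cue counting.
    """
    tokens = tokenize(normalized_text)
    if not tokens:
        return []
    if max_tokens is None:
        max_tokens = max((s.count(" ") + 1 for s in surface_map), default=1)
    taken = [False] * len(tokens)
    found: list[tuple[tuple[int, int], str, object]] = []
    for n in range(max_tokens, 0, -1):
        for i in range(0, len(tokens) - n + 1):
            if any(taken[i : i + n]):
                continue
            start, end = tokens[i].start, tokens[i + n - 1].end
            surface = normalized_text[start:end]
            payload = surface_map.get(surface)
            if payload is None:
                continue
            for k in range(i, i + n):
                taken[k] = True
            found.append(((start, end), surface, payload))
    found.sort(key=lambda m: m[0])
    return found


def sentence_texts(message: Message) -> list[str]:
    """The message's normalized sentences (splitting raw text if not preset)."""
    if message.sentences:
        return [normalize_text(s)[0] for s in message.sentences]
    return [normalize_text(s.text)[0] for s in split_sentences(message.raw_text)]


def detect_factor_mentions(
    message: Message, factor_lexicon: FactorLexicon
) -> list[FactorMention]:
    """Detect factor keywords in each sentence of a message."""
    surface_map = factor_lexicon.surface_map()
    mentions: list[FactorMention] = []
    for idx, sent in enumerate(sentence_texts(message)):
        for span, surface, entry in match_keywords(sent, surface_map):
            assert isinstance(entry, FactorKeywordEntry)
            mentions.append(
                FactorMention(
                    message_id=message.message_id,
                    sentence_index=idx,
                    span=span,
                    surface=surface,
                    matched_keyword=entry.keyword,
                    factor=entry.factor,
                    subcategory=entry.subcategory,
                )
            )
    return mentions


def count_factors(
    mentions: Iterable[FactorMention],
    group_keys: Sequence[str] = ("factor",),
    messages: Iterable[Message] | None = None,
    hospital_by_message: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Frequency table of mentions partitioned by the requested keys.

    ``region``/``year``/``month`` require ``messages`` (for metadata) and
    ``canonical_id`` requires ``hospital_by_message`` (message id -> hospital
    id of the message's resolved hospital).  The counts over any grouping sum
    to the total number of mentions.
    """
    for key in group_keys:
        if key not in GROUP_KEYS:
            raise ValueError(f"unknown group key {key!r}; valid: {GROUP_KEYS}")
    mentions = list(mentions)
    meta: dict[str, Message] = {}
    if messages is not None:
        meta = {m.message_id: m for m in messages}
    rows = []
    for m in mentions:
        row = {"factor": m.factor, "subcategory": m.subcategory}
        if meta:
            msg = meta.get(m.message_id)
            if msg is not None:
                row.update(region=msg.region, year=msg.year, month=msg.month)
        if hospital_by_message is not None:
            row["canonical_id"] = hospital_by_message.get(m.message_id)
        missing = [k for k in group_keys if k not in row]
        if missing:
            raise ValueError(
                f"group keys {missing} need message/hospital metadata "
                f"(mention {m.message_id!r})"
            )
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=[*group_keys, "count"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(list(group_keys), observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out
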