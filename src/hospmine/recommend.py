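"""Recommendation-type classification by sentiment-cue counting and mood flow.

Each sentence gets a polarity in {+1, 0, -1}: the sign of (positive cue
count - negative cue count), with a cue inside a negation window (within
``negation_window`` tokens after a negation marker) contributing with flipped
sign.  The *mood flow* of a message is its ordered sentence-polarity
sequence; the four-class label is assigned from which polarities appear:

* **positive** — some +1 sentence and no -1 (hospital recommended);
* **negative** — some -1 and no +1 (not recommended);
* **bilateral** — both polarities present (a within-message transition);
* **neutral** — no polarized sentence.

An alternative ``mode="last"`` lets the final polarized sentence decide
(useful when writers close with their verdict); the presence-based rule is
the default.  The binary reduction maps bilateral to negative — when praise
and complaint coexist, misclassifying a problem report as a recommendation
is the costlier error — and neutral messages are excluded.

Each detected factor mention inherits the polarity of its containing
sentence when that sentence is polarized, else the message's four-class
label.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

from .corpus import Message
from .factor_detect import FactorMention, match_keywords, sentence_texts
from .lexicons import SentimentLexicon
from .preprocess import tokenize

__all__ = [
    "RecommendationLabel",
    "PolarizedFactorInstance",
    "sentence_polarity",
    "mood_flow_classify",
    "to_binary",
    "assign_factor_polarity",
    "FOUR_CLASSES",
]

FOUR_CLASSES = ("positive", "neutral", "bilateral", "negative")


@dataclass(frozen=True)
class RecommendationLabel:
    """Per-message recommendation classification."""

    message_id: str
    four_class: str
    binary: str  # positive | negative | excluded
    sentence_polarities: tuple[int, ...]

    @property
    def flow(self) -> str:
        """The mood flow as a compact string, e.g. ``"+0-"``."""
        return "".join({1: "+", 0: "0", -1: "-"}[p] for p in self.sentence_polarities)


@dataclass(frozen=True)
class PolarizedFactorInstance:
    """A factor mention carrying its inherited recommendation polarity."""

    mention: FactorMention
    polarity: str  # four-class value


@lru_cache(maxsize=8)
def _cue_maps(lexicon: SentimentLexicon) -> tuple[dict[str, int], frozenset[str]]:
    from .preprocess import normalize_text

    surface_map: dict[str, int] = {}
    for cue in lexicon.positive_cues:
        surface_map[normalize_text(cue)[0]] = +1
    for cue in lexicon.negative_cues:
        surface_map[normalize_text(cue)[0]] = -1
    negations = frozenset(normalize_text(m)[0] for m in lexicon.negation_markers)
    return surface_map, negations


def sentence_polarity(
    sentence: str,
    lexicon: SentimentLexicon,
    negation_window: int = 2,
) -> tuple[int, int, int]:
    """Polarity of one normalized sentence with its cue counts.

    Returns ``(polarity, positive_count, negative_count)`` where counts are
    post-negation.  A tie (equal counts) is neutral: symmetric, and avoids a
    positive bias on genuinely mixed sentences.
    """
    surface_map, negations = _cue_maps(lexicon)
    tokens = tokenize(sentence)
    neg_token_idx = {
        i for i, t in enumerate(tokens) if t.text in negations
    }
    pos = neg = 0
    for span, _surface, sign in match_keywords(sentence, surface_map):
        cue_token = next(
            (i for i, t in enumerate(tokens) if t.start == span[0]), None
        )
        flipped = False
        if cue_token is not None and negations:
            lo = max(0, cue_token - negation_window)
            flipped = any(i in neg_token_idx for i in range(lo, cue_token))
        effective = -sign if flipped else sign
        if effective > 0:
            pos += 1
        else:
            neg += 1
    polarity = (pos > neg) - (pos < neg)
    return polarity, pos, neg


def mood_flow_classify(
    message: Message,
    lexicon: SentimentLexicon,
    negation_window: int = 2,
    mode: str = "presence",
) -> RecommendationLabel:
    """Classify a message from its ordered sentence polarities."""
    if mode not in ("presence", "last"):
        raise ValueError(f"unknown mood-flow mode {mode!r}")
    polarities = tuple(
        sentence_polarity(s, lexicon, negation_window)[0]
        for s in sentence_texts(message)
    )
    has_pos = any(p > 0 for p in polarities)
    has_neg = any(p < 0 for p in polarities)
    if mode == "last":
        polarized = [p for p in polarities if p != 0]
        four = (
            "neutral"
            if not polarized
            else ("positive" if polarized[-1] > 0 else "negative")
        )
    elif has_pos and has_neg:
        four = "bilateral"
    elif has_pos:
        four = "positive"
    elif has_neg:
        four = "negative"
    else:
        four = "neutral"
    return RecommendationLabel(
        message_id=message.message_id,
        four_class=four,
        binary=to_binary(four),
        sentence_polarities=polarities,
    )


def to_binary(four_class: str) -> str:
    """Reduce a four-class label to {positive, negative, excluded}.

    Bilateral counts as negative (conflicting messages are treated as
    non-recommendations); neutral messages are excluded from the binary view.
    """
    return {
        "positive": "positive",
        "negative": "negative",
        "bilateral": "negative",
        "neutral": "excluded",
    }[four_class]


def assign_factor_polarity(
    factor_mentions: Iterable[FactorMention],
    label: RecommendationLabel,
) -> list[PolarizedFactorInstance]:
    """Attach a polarity to every factor mention of a classified message.

    Sentence-first: a mention in a polarized sentence takes that sentence's
    sign; a mention in a neutral sentence falls back to the message's
    four-class label.
    """
    instances = []
    for m in factor_mentions:
        if m.message_id != label.message_id:
            raise ValueError(
                f"mention {m.message_id!r} does not belong to label {label.message_id!r}"
            )
        sp = (
            label.sentence_polarities[m.sentence_index]
            if m.sentence_index < len(label.sentence_polarities)
            else 0
        )
        if sp > 0:
            polarity = "positive"
        elif sp < 0:
            polarity = "negative"
        else:
            polarity = label.four_class
        instances.append(PolarizedFactorInstance(mention=m, polarity=polarity))
    return instances
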