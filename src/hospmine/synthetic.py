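"""Synthetic gold-labeled corpus generator.

No public corpus of the kind this pipeline consumes exists, so every stage
is exercised against generated data whose ground truth is known by
construction.  The generator emulates the *structural and statistical*
properties the pipeline depends on — threads of a few short messages each,
region and year-month metadata, hospital mentions written as (possibly
typo-corrupted) dictionary aliases, planted quality-factor keywords, and
sentiment cues arranged to produce a chosen four-class polarity mixture —
not linguistic realism: message text is English-like filler-token sequences.

Defaults mirror the study conditions: 5.59 messages per thread on average,
18.45% of messages carrying at least one quality-factor keyword, and a
four-class mixture of 36% positive and 8% negative-or-bilateral (5% + 3%),
the remainder neutral, over an April 2007 – May 2013 posting window.

Everything is driven by one explicitly passed seeded generator; the same
seed reproduces the corpus byte for byte.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corpus import Message, Thread
from .hospital_ner import fuzzy_threshold, match_hospital
from .lexicons import (
    FactorLexicon,
    HospitalLexicon,
    SentimentLexicon,
    REGIONS,
    default_lexicon_path,
    load_factor_lexicon,
    load_hospital_lexicon,
    load_sentiment_lexicon,
)

__all__ = [
    "GeneratorConfig",
    "GoldHospital",
    "GoldFactor",
    "GoldRecord",
    "ConfigError",
    "default_lexicons",
    "corrupt_alias",
    "generate_corpus",
    "generate_cooccurrence_corpus",
    "DISTRACTOR_VOCAB",
]

import datetime as _dt


class ConfigError(ValueError):
    """Raised for infeasible generator configurations."""


#: Filler vocabulary for message text.  Words are deliberately long and
#: unrelated to the bundled lexicons so that no filler n-gram falls within
#: the fuzzy threshold of a hospital alias (verified by the test suite).
DISTRACTOR_VOCAB = (
    "yesterday", "afternoon", "question", "anybody", "together", "weather",
    "morning", "holiday", "stroller", "playground", "neighborhood", "downtown",
    "building", "elevator", "umbrella", "calendar", "notebook", "picture",
    "window", "garden", "coffee", "library", "bicycle", "mountain", "river",
    "market", "station", "ticket", "journey", "evening", "sister", "brother",
    "grandmother", "cousin", "teacher", "lunchbox", "blanket", "pajamas",
    "birthday", "weekend",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the synthetic corpus.

    The polarity mixture and structural rates default to the observed corpus
    shape (messages/thread 5.59; 18.45% of messages containing factor clues;
    36% positive and 8% negative-including-bilateral four-class shares).
    """

    seed: int = 0
    regions: tuple[str, ...] = REGIONS
    n_threads_per_region: int = 20
    messages_per_thread_mean: float = 5.59
    sentences_min: int = 1
    sentences_max: int = 5
    hospital_mention_prob: float = 0.8
    typo_rate: float = 0.0
    max_edit_ops: int = 1
    factor_message_prob: float = 0.1845
    max_factor_mentions: int = 3
    equivalent_prob: float = 0.25
    p_positive: float = 0.36
    p_negative: float = 0.05
    p_bilateral: float = 0.03
    max_rel_distance: float = 0.25
    plant_in_polarized: bool = False
    factor_keyword_weights: tuple[tuple[str, float], ...] | None = None
    period: tuple[tuple[int, int], tuple[int, int]] = ((2007, 4), (2013, 5))
    distractor_vocab: tuple[str, ...] = DISTRACTOR_VOCAB

    @property
    def p_neutral(self) -> float:
        return 1.0 - self.p_positive - self.p_negative - self.p_bilateral

    def validate(self) -> None:
        probs = {
            "hospital_mention_prob": self.hospital_mention_prob,
            "typo_rate": self.typo_rate,
            "factor_message_prob": self.factor_message_prob,
            "equivalent_prob": self.equivalent_prob,
            "p_positive": self.p_positive,
            "p_negative": self.p_negative,
            "p_bilateral": self.p_bilateral,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.p_neutral < -1e-9:
            raise ConfigError("four-class mixture sums to more than 1")
        if self.p_bilateral > 0 and self.sentences_max < 2:
            raise ConfigError(
                "bilateral messages need at least 2 sentences; raise sentences_max"
            )
        if not 1 <= self.sentences_min <= self.sentences_max:
            raise ConfigError("need 1 <= sentences_min <= sentences_max")
        if self.messages_per_thread_mean < 1:
            raise ConfigError("messages_per_thread_mean must be >= 1")
        if self.max_edit_ops < 0:
            raise ConfigError("max_edit_ops must be >= 0")


@dataclass(frozen=True)
class GoldHospital:
    """Gold annotation for one planted hospital mention."""

    canonical_id: str
    alias: str
    surface: str
    span: tuple[int, int]  # in normalized message text
    sentence_index: int
    corrupted: bool
    n_ops: int


@dataclass(frozen=True)
class GoldFactor:
    """Gold annotation for one planted factor keyword."""

    factor: str
    subcategory: str
    keyword: str
    surface: str
    sentence_index: int
    span: tuple[int, int]  # in normalized sentence text
    polarity: str  # four-class value the instance should inherit


@dataclass(frozen=True)
class GoldRecord:
    """Everything the generator knows about one message."""

    message_id: str
    retained: bool
    four_class: str
    binary: str
    sentence_polarities: tuple[int, ...]
    hospitals: tuple[GoldHospital, ...]
    factors: tuple[GoldFactor, ...]
    ambiguous: bool = False


def default_lexicons() -> tuple[HospitalLexicon, FactorLexicon, SentimentLexicon]:
    """The small bundled stand-in lexicons (hospitals, factors, sentiment)."""
    return (
        load_hospital_lexicon(default_lexicon_path("hospitals")),
        load_factor_lexicon(default_lexicon_path("factors")),
        load_sentiment_lexicon(default_lexicon_path("sentiment")),
    )


def corrupt_alias(alias: str, n_ops: int, rng: np.random.Generator) -> str:
    """Apply exactly ``n_ops`` random character edits to an alias.

    Edits are unit insert/delete/substitute of lowercase letters, restricted
    to non-space positions so the token structure (and hence the whitespace
    normalization) of the surface stays stable.  The result is never empty,
    and its edit distance from the alias is at most ``n_ops`` (edits may
    partially cancel).
    """
    if n_ops < 0:
        raise ValueError("n_ops must be >= 0")
    chars = list(alias)
    letters = string.ascii_lowercase
    for _ in range(n_ops):
        positions = [i for i, c in enumerate(chars) if c != " "]
        ops = ["insert", "substitute"]
        if len(positions) > 1:
            ops.append("delete")
        op = ops[rng.integers(len(ops))]
        if op == "insert":
            i = positions[rng.integers(len(positions))]
            chars.insert(i + rng.integers(2), letters[rng.integers(26)])
        elif op == "delete":
            i = positions[rng.integers(len(positions))]
            del chars[i]
        else:
            i = positions[rng.integers(len(positions))]
            old = chars[i]
            new = old
            while new == old:
                new = letters[rng.integers(26)]
            chars[i] = new
    return "".join(chars)


def _month_range(period) -> list[tuple[int, int]]:
    (y0, m0), (y1, m1) = period
    months = []
    y, m = y0, m0
    while (y, m) <= (y1, m1):
        months.append((y, m))
        m += 1
        if m > 12:
            y, m = y + 1, 1
    if not months:
        raise ConfigError(f"empty posting period {period}")
    return months


def _choice(rng: np.random.Generator, seq: Sequence):
    return seq[int(rng.integers(len(seq)))]


def _filler(rng: np.random.Generator, vocab, n: int) -> list[str]:
    return [_choice(rng, vocab) for _ in range(n)]


class _Phrase:
    """A planted phrase; identity (not text) locates it after later insertions."""

    __slots__ = ("text", "sentence_index")

    def __init__(self, text: str, sentence_index: int) -> None:
        self.text = text
        self.sentence_index = sentence_index

    def __str__(self) -> str:
        return self.text


class _MessageBuilder:
    """Assembles one message sentence by sentence, tracking char offsets.

    Sentences are lists of *elements*: filler words (str) or planted
    :class:`_Phrase` objects.  Spans are resolved positionally by element
    identity after all insertions, so the same surface may legitimately
    appear several times.
    """

    def __init__(self) -> None:
        self.sentences: list[list] = []  # elements, lowercase

    def add_sentence(self, words: list[str]) -> int:
        self.sentences.append(list(words))
        return len(self.sentences) - 1

    def insert_phrase(self, sentence_index: int, phrase: str, rng) -> _Phrase:
        """Insert at a random element position; returns the identity marker."""
        elements = self.sentences[sentence_index]
        marker = _Phrase(phrase, sentence_index)
        elements.insert(int(rng.integers(len(elements) + 1)), marker)
        return marker

    def sentence_span(self, marker: _Phrase) -> tuple[int, int]:
        """Span of the planted phrase within its normalized sentence text."""
        elements = self.sentences[marker.sentence_index]
        start = 0
        for e in elements:
            if e is marker:
                return start, start + len(marker.text)
            start += len(str(e)) + 1
        raise RuntimeError(f"lost phrase {marker.text!r}")

    def message_span(self, marker: _Phrase) -> tuple[int, int]:
        """Span of the planted phrase within the normalized message text."""
        offset = sum(
            len(self._sentence_text(i)) + 2  # '.' ends a sentence, ' ' joins
            for i in range(marker.sentence_index)
        )
        s, e = self.sentence_span(marker)
        return offset + s, offset + e

    def _sentence_text(self, i: int) -> str:
        return " ".join(str(e) for e in self.sentences[i])

    def render(self, rng: np.random.Generator) -> str:
        """Raw text: sentences joined with '. '; random word casing as noise.

        Only ASCII case is touched, so the normalized text equals the
        lowercase render and all recorded offsets stay valid.
        """
        rendered = []
        for elements in self.sentences:
            out_words = []
            for e in elements:
                w = str(e)
                roll = rng.random()
                if roll < 0.15:
                    out_words.append(w.upper())
                elif roll < 0.45:
                    out_words.append(w.capitalize())
                else:
                    out_words.append(w)
            rendered.append(" ".join(out_words) + ".")
        return " ".join(rendered)


def _plan_polarities(
    four_class: str, n_sentences: int, rng: np.random.Generator
) -> list[int]:
    plan = [0] * n_sentences
    if four_class == "positive":
        plan[int(rng.integers(n_sentences))] = 1
    elif four_class == "negative":
        plan[int(rng.integers(n_sentences))] = -1
    elif four_class == "bilateral":
        i, j = rng.choice(n_sentences, size=2, replace=False)
        plan[int(i)] = 1
        plan[int(j)] = -1
    return plan


def _pick_typo_surface(
    alias: str,
    entry_id: str,
    hospitals: HospitalLexicon,
    region: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Corrupt an alias so that it still resolves uniquely to its hospital."""
    limit = fuzzy_threshold(alias, cfg.max_rel_distance)
    ops = int(rng.integers(1, cfg.max_edit_ops + 1)) if cfg.max_edit_ops >= 1 else 0
    ops = min(ops, limit)
    for _ in range(10):
        surface = corrupt_alias(alias, ops, rng)
        if surface == alias:
            continue
        result = match_hospital(
            surface, hospitals, region=region, max_rel_distance=cfg.max_rel_distance
        )
        if result is not None and result.canonical_id == entry_id and not result.ambiguous:
            return surface, ops
    return alias, 0  # could not corrupt safely; fall back to the clean alias


def generate_corpus(
    config: GeneratorConfig,
    hospitals: HospitalLexicon | None = None,
    factors: FactorLexicon | None = None,
    sentiment: SentimentLexicon | None = None,
) -> tuple[list[Thread], list[Message], dict[str, GoldRecord]]:
    """Generate a gold-labeled corpus; deterministic given ``config.seed``.

    Returns ``(threads, messages, gold)`` with one :class:`GoldRecord` per
    message.  Factor keywords are planted in sentences whose inherited
    polarity equals the message's four-class label (so instance-level and
    message-level polarity mixtures coincide) unless
    ``config.plant_in_polarized`` is set, in which case sentences are chosen
    uniformly and the gold polarity follows the sentence-first inheritance
    rule.
    """
    config.validate()
    if hospitals is None or factors is None or sentiment is None:
        h, f, s = default_lexicons()
        hospitals = hospitals or h
        factors = factors or f
        sentiment = sentiment or s
    rng = np.random.default_rng(config.seed)
    months = _month_range(config.period)
    pos_cues = sorted(sentiment.positive_cues)
    neg_cues = sorted(sentiment.negative_cues)
    factor_entries = list(factors.entries)
    weights = None
    if config.factor_keyword_weights is not None:
        wmap = dict(config.factor_keyword_weights)
        factor_entries = [e for e in factor_entries if e.keyword in wmap]
        missing = set(wmap) - {e.keyword for e in factor_entries}
        if missing:
            raise ConfigError(f"weights reference unknown keywords: {sorted(missing)}")
        raw = np.array([wmap[e.keyword] for e in factor_entries], dtype=float)
        weights = raw / raw.sum()
    mixture = np.array(
        [config.p_positive, config.p_negative, config.p_bilateral, config.p_neutral]
    )
    mixture = np.clip(mixture, 0, None)
    mixture = mixture / mixture.sum()
    classes = ("positive", "negative", "bilateral", "neutral")

    threads: list[Thread] = []
    messages: list[Message] = []
    gold: dict[str, GoldRecord] = {}
    msg_counter = 0
    for region in config.regions:
        region_hospitals = hospitals.by_region(region)
        for t_idx in range(config.n_threads_per_region):
            thread_id = f"{region[:3].upper()}-T{t_idx:04d}"
            year, month = _choice(rng, months)
            title = " ".join(_filler(rng, config.distractor_vocab, 3))
            n_msgs = 1 + int(rng.poisson(config.messages_per_thread_mean - 1.0))
            thread = Thread(thread_id=thread_id, title=title, region=region)
            for _ in range(n_msgs):
                msg_counter += 1
                message_id = f"M{msg_counter:06d}"
                four_class = classes[int(rng.choice(4, p=mixture))]
                has_hospital = bool(region_hospitals) and rng.random() < config.hospital_mention_prob
                has_factor = rng.random() < config.factor_message_prob
                n_sent = int(rng.integers(config.sentences_min, config.sentences_max + 1))
                if four_class == "bilateral":
                    n_sent = max(n_sent, 2)
                    if has_factor and not config.plant_in_polarized:
                        n_sent = max(n_sent, 3)  # need a neutral sentence
                plan = _plan_polarities(four_class, n_sent, rng)

                builder = _MessageBuilder()
                for polarity in plan:
                    words = _filler(rng, config.distractor_vocab, int(rng.integers(4, 9)))
                    builder.add_sentence(words)
                    idx = len(builder.sentences) - 1
                    if polarity > 0:
                        builder.insert_phrase(idx, _choice(rng, pos_cues).casefold(), rng)
                    elif polarity < 0:
                        builder.insert_phrase(idx, _choice(rng, neg_cues).casefold(), rng)

                gold_factors: list[GoldFactor] = []
                factor_phrases: list[tuple[object, object]] = []  # (marker, entry)
                if has_factor and factor_entries:
                    n_f = 1 + int(rng.integers(config.max_factor_mentions))
                    if config.plant_in_polarized:
                        candidate_sents = list(range(n_sent))
                    elif four_class == "bilateral":
                        candidate_sents = [i for i, p in enumerate(plan) if p == 0]
                    else:
                        candidate_sents = list(range(n_sent))
                    for _ in range(n_f):
                        if weights is None:
                            entry = _choice(rng, factor_entries)
                        else:
                            entry = factor_entries[int(rng.choice(len(factor_entries), p=weights))]
                        surface = entry.keyword
                        if entry.equivalents and rng.random() < config.equivalent_prob:
                            surface = _choice(rng, sorted(entry.equivalents))
                        s_idx = int(_choice(rng, candidate_sents))
                        marker = builder.insert_phrase(s_idx, surface.casefold(), rng)
                        factor_phrases.append((marker, entry))

                gold_hospitals: list[GoldHospital] = []
                hospital_phrase = None  # (marker, entry, alias, corrupted, ops)
                if has_hospital:
                    entry = _choice(rng, region_hospitals)
                    alias = _choice(rng, sorted(entry.aliases)).casefold()
                    surface, ops = alias, 0
                    if config.typo_rate > 0 and rng.random() < config.typo_rate:
                        surface, ops = _pick_typo_surface(
                            alias, entry.canonical_id, hospitals, region, config, rng
                        )
                    s_idx = int(rng.integers(n_sent))
                    marker = builder.insert_phrase(s_idx, surface, rng)
                    hospital_phrase = (marker, entry, alias, ops > 0, ops)

                # spans are resolved after all insertions so offsets are final
                for marker, entry in factor_phrases:
                    s_idx = marker.sentence_index
                    if config.plant_in_polarized:
                        sp = plan[s_idx]
                        inherited = (
                            "positive" if sp > 0 else "negative" if sp < 0 else four_class
                        )
                    else:
                        inherited = four_class
                    gold_factors.append(
                        GoldFactor(
                            factor=entry.factor,
                            subcategory=entry.subcategory,
                            keyword=entry.keyword,
                            surface=marker.text,
                            sentence_index=s_idx,
                            span=builder.sentence_span(marker),
                            polarity=inherited,
                        )
                    )
                if hospital_phrase is not None:
                    marker, entry, alias, corrupted, ops = hospital_phrase
                    gold_hospitals.append(
                        GoldHospital(
                            canonical_id=entry.canonical_id,
                            alias=alias,
                            surface=marker.text,
                            span=builder.message_span(marker),
                            sentence_index=marker.sentence_index,
                            corrupted=corrupted,
                            n_ops=ops,
                        )
                    )

                raw_text = builder.render(rng)
                messages.append(
                    Message(
                        message_id=message_id,
                        thread_id=thread_id,
                        region=region,
                        posted_at=_dt.date(year, month, 1 + int(rng.integers(28))),
                        raw_text=raw_text,
                    )
                )
                thread.message_ids.append(message_id)
                binary = {
                    "positive": "positive",
                    "negative": "negative",
                    "bilateral": "negative",
                    "neutral": "excluded",
                }[four_class]
                gold[message_id] = GoldRecord(
                    message_id=message_id,
                    retained=bool(gold_hospitals),
                    four_class=four_class,
                    binary=binary,
                    sentence_polarities=tuple(plan),
                    hospitals=tuple(gold_hospitals),
                    factors=tuple(gold_factors),
                )
            threads.append(thread)
    return threads, messages, gold


def generate_cooccurrence_corpus(
    term: str,
    hospital_probs: Mapping[str, float],
    filler_id: str,
    n_threads: int,
    seed: int,
    region: str,
    hospitals: HospitalLexicon,
    sentiment: SentimentLexicon,
    vocab: tuple[str, ...] = DISTRACTOR_VOCAB,
) -> tuple[list[Thread], list[Message], dict[str, float]]:
    """Negative threads containing ``term``, each co-mentioning at most one
    planted hospital.

    With probability ``hospital_probs[cid]`` the thread's hospital is ``cid``;
    otherwise it is ``filler_id`` (so every thread still has a resolvable,
    retained message).  Recovering the per-hospital co-occurrence ratios from
    the pipeline should reproduce ``hospital_probs`` up to sampling error.
    """
    total = sum(hospital_probs.values())
    if total > 1.0 + 1e-9:
        raise ConfigError("hospital inclusion probabilities sum to more than 1")
    rng = np.random.default_rng(seed)
    ids = sorted(hospital_probs)
    probs = np.array([hospital_probs[i] for i in ids] + [1.0 - total])
    choices = ids + [filler_id]
    neg_cues = sorted(sentiment.negative_cues)
    threads: list[Thread] = []
    messages: list[Message] = []
    for t in range(n_threads):
        thread_id = f"CO-T{t:05d}"
        cid = choices[int(rng.choice(len(choices), p=probs))]
        entry = hospitals.by_id[cid]
        alias = sorted(entry.aliases)[0].casefold()
        words = _filler(rng, vocab, 5)
        text = (
            f"{' '.join(words[:2])} {term.casefold()} {alias} "
            f"{_choice(rng, neg_cues).casefold()} {' '.join(words[2:])}."
        )
        message_id = f"CM{t:05d}"
        messages.append(
            Message(
                message_id=message_id,
                thread_id=thread_id,
                region=region,
                posted_at=_dt.date(2010, 1 + int(rng.integers(12)), 1),
                raw_text=text,
            )
        )
        threads.append(
            Thread(
                thread_id=thread_id,
                title=" ".join(_filler(rng, vocab, 3)),
                region=region,
                message_ids=[message_id],
            )
        )
    return threads, messages, dict(hospital_probs)
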