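"""Dictionaries the pipeline depends on: hospitals, quality factors, sentiment cues.

Three lexicons drive the whole pipeline:

* a **hospital dictionary** mapping canonical hospital names (plus the
  acronyms, abbreviations and misspellings users actually write) to stable
  ids, with the hospital's region;
* a **quality-factor keyword dictionary** for the six social-media-based
  hospital service quality factors — service, professionalism, process,
  environment, impression, popularity — whose keywords carry subcategory
  codes ``f1``–``f29`` (functional: the first four factors) or ``e1``–``e10``
  (emotional: impression and popularity);
* a **sentiment lexicon** of cue phrases for and against recommendation,
  with an optional negation-marker set.

On-disk format is UTF-8 TSV with a header row; multi-valued cells
(aliases, equivalents) are pipe-delimited.  All matching is done on
normalized text (casefold + whitespace collapse), applied identically at
load and at query time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .preprocess import normalize_text

__all__ = [
    "FACTORS",
    "FUNCTIONAL_FACTORS",
    "EMOTIONAL_FACTORS",
    "REGIONS",
    "HospitalEntry",
    "FactorKeywordEntry",
    "SentimentLexicon",
    "HospitalLexicon",
    "FactorLexicon",
    "LexiconError",
    "load_hospital_lexicon",
    "write_hospital_lexicon",
    "load_factor_lexicon",
    "write_factor_lexicon",
    "load_sentiment_lexicon",
    "write_sentiment_lexicon",
    "validate_lexicons",
    "default_lexicon_path",
]

#: The six social-media-based hospital service quality factors.
FUNCTIONAL_FACTORS = ("service", "professionalism", "process", "environment")
EMOTIONAL_FACTORS = ("impression", "popularity")
FACTORS = FUNCTIONAL_FACTORS + EMOTIONAL_FACTORS

#: Default region list (the six big-city districts of the study setting).
REGIONS = ("Seoul", "Daegu", "Busan", "Daejeon", "Incheon", "Gwangju")


class LexiconError(ValueError):
    """Raised when a lexicon file fails validation."""


def _norm(text: str) -> str:
    return normalize_text(text)[0]


@dataclass(frozen=True)
class HospitalEntry:
    """One hospital: canonical name, region, and the surface forms users write."""

    canonical_id: str
    canonical_name: str
    region: str
    aliases: frozenset[str]

    def __post_init__(self) -> None:
        if not self.canonical_name.strip():
            raise LexiconError(f"{self.canonical_id}: empty canonical name")
        if any(not a for a in self.aliases):
            raise LexiconError(f"{self.canonical_id}: empty alias")
        if self.canonical_name not in self.aliases:
            object.__setattr__(
                self, "aliases", self.aliases | {self.canonical_name}
            )


@dataclass(frozen=True)
class FactorKeywordEntry:
    """One quality-factor keyword with its factor, subcategory code, and equivalents."""

    keyword: str
    factor: str
    subcategory: str
    equivalents: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.keyword.strip():
            raise LexiconError("empty keyword")
        if self.factor not in FACTORS:
            raise LexiconError(f"unknown factor {self.factor!r}")
        _check_subcategory(self.factor, self.subcategory)

    @property
    def surfaces(self) -> frozenset[str]:
        return self.equivalents | {self.keyword}


def _check_subcategory(factor: str, code: str) -> None:
    """f1–f29 belong to the functional factors, e1–e10 to the emotional ones."""
    kind = code[:1]
    if kind == "f" and code[1:].isdigit() and 1 <= int(code[1:]) <= 29:
        if factor not in FUNCTIONAL_FACTORS:
            raise LexiconError(
                f"subcategory {code} (functional) cannot attach to factor {factor!r}"
            )
        return
    if kind == "e" and code[1:].isdigit() and 1 <= int(code[1:]) <= 10:
        if factor not in EMOTIONAL_FACTORS:
            raise LexiconError(
                f"subcategory {code} (emotional) cannot attach to factor {factor!r}"
            )
        return
    raise LexiconError(f"invalid subcategory code {code!r}")


@dataclass(frozen=True)
class SentimentLexicon:
    """Cue phrases for/against recommendation, plus optional negation markers."""

    positive_cues: frozenset[str]
    negative_cues: frozenset[str]
    negation_markers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = self.positive_cues & self.negative_cues
        if overlap:
            raise LexiconError(f"cues in both polarities: {sorted(overlap)}")
        if not self.positive_cues or not self.negative_cues:
            raise LexiconError("both cue sets must be nonempty")

    def swapped(self) -> "SentimentLexicon":
        """The lexicon with positive and negative cue sets exchanged."""
        return SentimentLexicon(
            self.negative_cues, self.positive_cues, self.negation_markers
        )


class HospitalLexicon:
    """Indexed collection of :class:`HospitalEntry` with normalized lookup."""

    def __init__(self, entries: Iterable[HospitalEntry]):
        self.entries: list[HospitalEntry] = list(entries)
        seen: set[str] = set()
        for e in self.entries:
            if e.canonical_id in seen:
                raise LexiconError(f"duplicate canonical_id {e.canonical_id!r}")
            seen.add(e.canonical_id)
        self.by_id: dict[str, HospitalEntry] = {
            e.canonical_id: e for e in self.entries
        }
        self._by_canonical: dict[str, list[HospitalEntry]] = {}
        self._by_alias: dict[str, list[HospitalEntry]] = {}
        for e in self.entries:
            self._by_canonical.setdefault(_norm(e.canonical_name), []).append(e)
            for alias in e.aliases:
                bucket = self._by_alias.setdefault(_norm(alias), [])
                if e not in bucket:
                    bucket.append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_region(self, region: str) -> list[HospitalEntry]:
        return [e for e in self.entries if e.region == region]

    def lookup_canonical(self, surface: str) -> list[HospitalEntry]:
        """Entries whose canonical name equals ``surface`` after normalization."""
        return list(self._by_canonical.get(_norm(surface), ()))

    def lookup_alias(self, surface: str) -> list[HospitalEntry]:
        """Entries with any alias equal to ``surface`` after normalization."""
        return list(self._by_alias.get(_norm(surface), ()))

    def alias_pairs(self) -> list[tuple[str, HospitalEntry]]:
        """All (normalized alias, entry) pairs, for fuzzy scanning."""
        return [
            (alias, e) for alias, bucket in self._by_alias.items() for e in bucket
        ]

    def all_surfaces(self) -> set[str]:
        return set(self._by_alias)


class FactorLexicon:
    """Indexed collection of :class:`FactorKeywordEntry`.

    Lookup keys are the normalized keyword and every normalized equivalent;
    each key resolves to the owning entry.
    """

    def __init__(self, entries: Iterable[FactorKeywordEntry]):
        self.entries: list[FactorKeywordEntry] = list(entries)
        seen: set[tuple[str, str, str]] = set()
        self._by_surface: dict[str, FactorKeywordEntry] = {}
        for e in self.entries:
            key = (e.keyword, e.factor, e.subcategory)
            if key in seen:
                raise LexiconError(f"duplicate factor entry {key}")
            seen.add(key)
            for surface in e.surfaces:
                ns = _norm(surface)
                if not ns:
                    raise LexiconError(f"{e.keyword!r}: empty equivalent")
                other = self._by_surface.get(ns)
                if other is not None and other is not e:
                    raise LexiconError(
                        f"surface {surface!r} maps to both {other.keyword!r} "
                        f"and {e.keyword!r}"
                    )
                self._by_surface[ns] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def lookup(self, surface: str) -> FactorKeywordEntry | None:
        """The entry owning ``surface`` (keyword or equivalent), if any."""
        return self._by_surface.get(_norm(surface))

    def surface_map(self) -> Mapping[str, FactorKeywordEntry]:
        return dict(self._by_surface)

    def all_surfaces(self) -> set[str]:
        return set(self._by_surface)


# ---------------------------------------------------------------------------
# TSV I/O


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> list[dict[str, str]]:
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        missing = [c for c in required if c not in cols]
        if missing:
            raise LexiconError(f"{path}: missing columns {missing}")
        return [{k: (v or "") for k, v in row.items()} for row in reader]


def _split_multi(cell: str) -> list[str]:
    return [part.strip() for part in cell.split("|") if part.strip()]


def load_hospital_lexicon(path: str | Path) -> HospitalLexicon:
    """Load hospitals.tsv (canonical_id, canonical_name, region, aliases)."""
    rows = _read_tsv(path, ("canonical_id", "canonical_name", "region", "aliases"))
    entries = []
    for i, row in enumerate(rows, start=2):  # row 1 is the header
        cell = row["aliases"]
        aliases = _split_multi(cell)
        # an explicitly empty segment ("a||b", trailing "|") is a data error;
        # an empty cell just means "no aliases beyond the canonical name"
        if cell.strip() and any(not p.strip() for p in cell.split("|")):
            raise LexiconError(f"{path} row {i}: empty alias")
        try:
            entries.append(
                HospitalEntry(
                    canonical_id=row["canonical_id"].strip(),
                    canonical_name=row["canonical_name"].strip(),
                    region=row["region"].strip(),
                    aliases=frozenset(aliases) | {row["canonical_name"].strip()},
                )
            )
        except LexiconError as err:
            raise LexiconError(f"{path} row {i}: {err}") from None
    return HospitalLexicon(entries)


def write_hospital_lexicon(lexicon: HospitalLexicon, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["canonical_id", "canonical_name", "region", "aliases"])
        for e in lexicon.entries:
            writer.writerow(
                [e.canonical_id, e.canonical_name, e.region, "|".join(sorted(e.aliases))]
            )


def load_factor_lexicon(path: str | Path) -> FactorLexicon:
    """Load factors.tsv (keyword, factor, subcategory, equivalents)."""
    rows = _read_tsv(path, ("keyword", "factor", "subcategory", "equivalents"))
    entries = []
    for i, row in enumerate(rows, start=2):
        try:
            entries.append(
                FactorKeywordEntry(
                    keyword=row["keyword"].strip(),
                    factor=row["factor"].strip(),
                    subcategory=row["subcategory"].strip(),
                    equivalents=frozenset(_split_multi(row["equivalents"])),
                )
            )
        except LexiconError as err:
            raise LexiconError(f"{path} row {i}: {err}") from None
    return FactorLexicon(entries)


def write_factor_lexicon(lexicon: FactorLexicon, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["keyword", "factor", "subcategory", "equivalents"])
        for e in lexicon.entries:
            writer.writerow(
                [e.keyword, e.factor, e.subcategory, "|".join(sorted(e.equivalents))]
            )


def load_sentiment_lexicon(path: str | Path) -> SentimentLexicon:
    """Load sentiment.tsv (cue, polarity) with polarity in {positive, negative, negation}."""
    rows = _read_tsv(path, ("cue", "polarity"))
    buckets: dict[str, set[str]] = {"positive": set(), "negative": set(), "negation": set()}
    for i, row in enumerate(rows, start=2):
        pol = row["polarity"].strip()
        cue = row["cue"].strip()
        if pol not in buckets:
            raise LexiconError(f"{path} row {i}: unknown polarity {pol!r}")
        if not cue:
            raise LexiconError(f"{path} row {i}: empty cue")
        buckets[pol].add(cue)
    return SentimentLexicon(
        frozenset(buckets["positive"]),
        frozenset(buckets["negative"]),
        frozenset(buckets["negation"]),
    )


def write_sentiment_lexicon(lexicon: SentimentLexicon, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cue", "polarity"])
        for cue in sorted(lexicon.positive_cues):
            writer.writerow([cue, "positive"])
        for cue in sorted(lexicon.negative_cues):
            writer.writerow([cue, "negative"])
        for cue in sorted(lexicon.negation_markers):
            writer.writerow([cue, "negation"])


def validate_lexicons(
    hospitals: HospitalLexicon,
    factors: FactorLexicon,
    sentiment: SentimentLexicon,
) -> list[str]:
    """Report cross-lexicon surface collisions as warnings (never errors).

    A hospital alias identical (after normalization) to a factor keyword or a
    sentiment cue would make the same span claimable by two detectors; such
    collisions are legal but worth flagging.
    """
    warnings: list[str] = []
    hospital_surfaces = hospitals.all_surfaces()
    factor_surfaces = factors.all_surfaces()
    cue_surfaces = {
        _norm(c)
        for c in sentiment.positive_cues | sentiment.negative_cues | sentiment.negation_markers
    }
    for s in sorted(hospital_surfaces & factor_surfaces):
        warnings.append(f"hospital alias collides with factor keyword: {s!r}")
    for s in sorted(hospital_surfaces & cue_surfaces):
        warnings.append(f"hospital alias collides with sentiment cue: {s!r}")
    for s in sorted(factor_surfaces & cue_surfaces):
        warnings.append(f"factor keyword collides with sentiment cue: {s!r}")
    return warnings


def default_lexicon_path(name: str) -> Path:
    """Path to one of the small bundled stand-in lexicons (hospitals/factors/sentiment)."""
    return Path(__file__).parent / "data" / f"{name}.tsv"
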