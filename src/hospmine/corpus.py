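"""Three-level corpus structure (threads -> messages -> sentences) and its I/O.

The on-disk format is JSON Lines: one self-describing record per line, with a
``kind`` field discriminating ``thread`` and ``message`` records.  Dates are
ISO-8601 strings; year-month precision is sufficient for the analytics, so a
bare ``YYYY-MM`` is accepted and normalized to the first of the month.

Raw inputs arriving as HTML pages are reduced to visible text with
:func:`strip_html` before entering the pipeline.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import lxml.etree
import lxml.html
import pandas as pd

__all__ = [
    "Message",
    "Thread",
    "CorpusError",
    "strip_html",
    "read_corpus",
    "write_corpus",
    "corpus_stats",
    "stats_from_counts",
]


class CorpusError(ValueError):
    """Raised on malformed corpus files or broken thread/message references."""


def _parse_date(value: str) -> _dt.date:
    value = value.strip()
    if re.fullmatch(r"\d{4}-\d{2}", value):
        value += "-01"
    try:
        return _dt.date.fromisoformat(value)
    except ValueError as err:
        raise CorpusError(f"unparseable date {value!r}") from err


@dataclass
class Message:
    """One community post: metadata, raw text, and (after preprocessing) sentences."""

    message_id: str
    thread_id: str
    region: str
    posted_at: _dt.date
    raw_text: str
    sentences: list[str] = field(default_factory=list)

    @property
    def year(self) -> int:
        return self.posted_at.year

    @property
    def month(self) -> int:
        return self.posted_at.month

    def to_record(self) -> dict:
        rec = {
            "kind": "message",
            "message_id": self.message_id,
            "thread_id": self.thread_id,
            "region": self.region,
            "posted_at": self.posted_at.isoformat(),
            "raw_text": self.raw_text,
        }
        if self.sentences:
            rec["sentences"] = list(self.sentences)
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "Message":
        return cls(
            message_id=str(rec["message_id"]),
            thread_id=str(rec["thread_id"]),
            region=str(rec["region"]),
            posted_at=_parse_date(str(rec["posted_at"])),
            raw_text=str(rec.get("raw_text", "")),
            sentences=list(rec.get("sentences", [])),
        )


@dataclass
class Thread:
    """A forum discussion: title, region, and its messages in posting order."""

    thread_id: str
    title: str
    region: str
    message_ids: list[str] = field(default_factory=list)

    def to_record(self) -> dict:
        return {
            "kind": "thread",
            "thread_id": self.thread_id,
            "title": self.title,
            "region": self.region,
            "message_ids": list(self.message_ids),
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Thread":
        return cls(
            thread_id=str(rec["thread_id"]),
            title=str(rec.get("title", "")),
            region=str(rec["region"]),
            message_ids=[str(m) for m in rec.get("message_ids", [])],
        )


# ---------------------------------------------------------------------------
# HTML stripping

_BLOCK_TAGS = {
    "p", "div", "br", "li", "ul", "ol", "tr", "table", "h1", "h2", "h3",
    "h4", "h5", "h6", "blockquote", "section", "article", "header", "footer",
    "dt", "dd", "form", "hr", "pre",
}
_DROP_TAGS = {"script", "style", "head", "title", "meta", "link", "img", "iframe", "noscript"}


def strip_html(document: str) -> str:
    """Reduce an HTML document to its visible text.

    Script/style/head contents are removed entirely, block-level element
    boundaries become newlines, entity references are decoded, and runs of
    blank lines are collapsed.  The parser is lenient: malformed markup is
    handled best-effort, and plain text passes through unchanged, which makes
    the operation idempotent.
    """
    if not document or not document.strip():
        return ""
    try:
        root = lxml.html.fromstring(document)
    except (lxml.etree.ParserError, ValueError):
        return _tidy(document)
    parts: list[str] = []
    _collect_text(root, parts)
    return _tidy("".join(parts))


def _collect_text(el, parts: list[str]) -> None:
    tag = el.tag if isinstance(el.tag, str) else ""
    if tag.lower() in _DROP_TAGS or isinstance(el, lxml.html.HtmlComment):
        if el.tail:
            parts.append(el.tail)
        return
    block = tag.lower() in _BLOCK_TAGS
    if block:
        parts.append("\n")
    if el.text:
        parts.append(el.text)
    for child in el:
        _collect_text(child, parts)
    if block:
        parts.append("\n")
    if el.tail:
        parts.append(el.tail)


def _tidy(text: str) -> str:
    # collapse horizontal whitespace per line, drop blank lines
    lines = [re.sub(r"[ \t\r\f\v]+", " ", ln).strip() for ln in text.split("\n")]
    return "\n".join(ln for ln in lines if ln)


# ---------------------------------------------------------------------------
# JSONL I/O


def read_corpus(path: str | Path) -> tuple[list[Thread], list[Message]]:
    """Read a JSONL corpus; input order of threads and messages is preserved.

    Raises :class:`CorpusError` with the offending line number on malformed
    lines, and on dangling references (a thread listing an unknown message id,
    or a message naming an unknown thread).
    """
    threads: list[Thread] = []
    messages: list[Message] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                kind = rec["kind"]
                if kind == "thread":
                    threads.append(Thread.from_record(rec))
                elif kind == "message":
                    messages.append(Message.from_record(rec))
                else:
                    raise CorpusError(f"unknown record kind {kind!r}")
            except (json.JSONDecodeError, KeyError, CorpusError, TypeError) as err:
                raise CorpusError(f"{path} line {lineno}: {err}") from None
    seen_msgs: set[str] = set()
    for m in messages:
        if m.message_id in seen_msgs:
            raise CorpusError(f"duplicate message_id {m.message_id!r}")
        seen_msgs.add(m.message_id)
    thread_ids = {t.thread_id for t in threads}
    for t in threads:
        for mid in t.message_ids:
            if mid not in seen_msgs:
                raise CorpusError(
                    f"thread {t.thread_id!r} references unknown message {mid!r}"
                )
    for m in messages:
        if m.thread_id not in thread_ids:
            raise CorpusError(
                f"message {m.message_id!r} references unknown thread {m.thread_id!r}"
            )
    return threads, messages


def write_corpus(
    threads: Iterable[Thread], messages: Iterable[Message], path: str | Path
) -> None:
    """Write threads then messages, one JSON record per line (stable key order)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for t in threads:
            fh.write(json.dumps(t.to_record(), ensure_ascii=False, sort_keys=True))
            fh.write("\n")
        for m in messages:
            fh.write(json.dumps(m.to_record(), ensure_ascii=False, sort_keys=True))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Statistics


def corpus_stats(
    threads: Iterable[Thread],
    messages: Iterable[Message],
    messages_with_factors: set[str] | None = None,
) -> pd.DataFrame:
    """Per-region corpus statistics plus Total and Average rows.

    Columns: ``threads``, ``messages``, ``messages_per_thread`` (ratio of the
    two counts, rounded to 2 decimals), and — when ``messages_with_factors``
    (ids of messages containing at least one quality-factor mention) is given
    — ``messages_with_factors`` and its percentage of all messages.

    The Average row holds the arithmetic mean over regions (each region
    weighted equally); the ratio cell of the Total row is left empty, and the
    factor-share percentage appears on the Total row, matching the summary
    presentation this table follows.
    """
    threads = list(threads)
    messages = list(messages)
    regions = list(dict.fromkeys([t.region for t in threads] + [m.region for m in messages]))
    thread_counts = {r: sum(1 for t in threads if t.region == r) for r in regions}
    message_counts = {r: sum(1 for m in messages if m.region == r) for r in regions}
    factor_counts = None
    if messages_with_factors is not None:
        factor_counts = {
            r: sum(
                1
                for m in messages
                if m.region == r and m.message_id in messages_with_factors
            )
            for r in regions
        }
    return stats_from_counts(thread_counts, message_counts, factor_counts)


def stats_from_counts(
    thread_counts: Mapping[str, int],
    message_counts: Mapping[str, int],
    factor_counts: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """The summary table of :func:`corpus_stats` from per-region counts.

    Useful when only the counts of a corpus are available, not the corpus
    itself.
    """
    rows = []
    for region in thread_counts:
        n_t = thread_counts[region]
        n_m = message_counts.get(region, 0)
        row = {
            "region": region,
            "threads": n_t,
            "messages": n_m,
            "messages_per_thread": round(n_m / n_t, 2) if n_t else float("nan"),
        }
        if factor_counts is not None:
            row["messages_with_factors"] = factor_counts.get(region, 0)
        rows.append(row)
    df = pd.DataFrame(rows)
    messages_with_factors = factor_counts  # reuse the total/average block below
    if df.empty:
        cols = ["region", "threads", "messages", "messages_per_thread"]
        if messages_with_factors is not None:
            cols.append("messages_with_factors")
        return pd.DataFrame(columns=cols)
    total = {
        "region": "Total",
        "threads": int(df["threads"].sum()),
        "messages": int(df["messages"].sum()),
        "messages_per_thread": float("nan"),
    }
    average = {
        "region": "Average",
        "threads": round(float(df["threads"].mean()), 2),
        "messages": round(float(df["messages"].mean()), 2),
        "messages_per_thread": round(float(df["messages_per_thread"].mean()), 2),
    }
    if messages_with_factors is not None:
        n_with = int(df["messages_with_factors"].sum())
        total["messages_with_factors"] = n_with
        total["factor_share_pct"] = round(100.0 * n_with / total["messages"], 2)
    return pd.concat([df, pd.DataFrame([total, average])], ignore_index=True)
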