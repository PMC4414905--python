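"""Region/time aggregations over polarized factor instances.

All analytics run off a flat *instance table* (one row per polarized factor
mention, enriched with message metadata) built by
:func:`build_instance_table`.  Percentages are kept at two-decimal precision
internally; any coarser rounding belongs to the formatting layer.

Denominators: by default, distribution percentages are taken over
*classified* instances (those whose binary reduction is not ``excluded``,
i.e. neutral-message instances are left out); ``include_neutral=True``
switches to all instances.  Both modes are provided because summary shares
can plausibly be quoted either way.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import Message, Thread
from .factor_detect import FactorMention
from .hospital_ner import HospitalMention
from .lexicons import FACTORS
from .preprocess import normalize_text, tokenize
from .recommend import PolarizedFactorInstance, RecommendationLabel, to_binary

__all__ = [
    "build_instance_table",
    "factor_distribution",
    "negative_share",
    "item_share",
    "cooccurrence",
    "recommendation_share",
]


def build_instance_table(
    instances: Iterable[PolarizedFactorInstance],
    messages: Iterable[Message],
    hospital_mentions: Iterable[HospitalMention] = (),
) -> pd.DataFrame:
    """One row per polarized factor instance, with message metadata attached.

    Columns: message_id, thread_id, region, year, month, factor, subcategory,
    keyword, sentence_index, polarity (four-class), binary, canonical_id.
    When a message has several hospital mentions the instance is attributed
    to the earliest unambiguous one.
    """
    meta = {m.message_id: m for m in messages}
    first_hospital: dict[str, str] = {}
    for hm in sorted(hospital_mentions, key=lambda h: (h.message_id, h.span)):
        if not hm.ambiguous:
            first_hospital.setdefault(hm.message_id, hm.canonical_id)
    rows = []
    for inst in instances:
        m = inst.mention
        msg = meta.get(m.message_id)
        if msg is None:
            raise ValueError(f"instance references unknown message {m.message_id!r}")
        rows.append(
            {
                "message_id": m.message_id,
                "thread_id": msg.thread_id,
                "region": msg.region,
                "year": msg.year,
                "month": msg.month,
                "factor": m.factor,
                "subcategory": m.subcategory,
                "keyword": m.matched_keyword,
                "sentence_index": m.sentence_index,
                "polarity": inst.polarity,
                "binary": to_binary(inst.polarity),
                "canonical_id": first_hospital.get(m.message_id),
            }
        )
    cols = [
        "message_id", "thread_id", "region", "year", "month", "factor",
        "subcategory", "keyword", "sentence_index", "polarity", "binary",
        "canonical_id",
    ]
    return pd.DataFrame(rows, columns=cols)


def _classified(table: pd.DataFrame, include_neutral: bool) -> pd.DataFrame:
    return table if include_neutral else table[table["binary"] != "excluded"]


def factor_distribution(
    table: pd.DataFrame,
    by: Sequence[str] = ("region",),
    polarity_filter: str | None = None,
    include_neutral: bool = False,
) -> pd.DataFrame:
    """Per-group percentage share of each factor.

    ``share(factor | group) = 100 * count(factor, group) / count(group)``;
    shares within a group sum to 100.  ``polarity_filter`` restricts the
    instances first (e.g. ``"negative"`` — binary view — for negative-attitude
    distributions by year).  Empty groups are omitted.
    """
    sub = _classified(table, include_neutral)
    if polarity_filter is not None:
        sub = sub[(sub["binary"] == polarity_filter) | (sub["polarity"] == polarity_filter)]
    if sub.empty:
        return pd.DataFrame(columns=[*by, "factor", "count", "share_pct"])
    grouped = (
        sub.groupby([*by, "factor"], observed=True).size().rename("count").reset_index()
    )
    totals = grouped.groupby(list(by), observed=True)["count"].transform("sum")
    grouped["share_pct"] = (100.0 * grouped["count"] / totals).round(2)
    return grouped


def negative_share(
    table: pd.DataFrame,
    by: Sequence[str] = ("year",),
    include_neutral: bool = False,
) -> pd.DataFrame:
    """Percentage of instances with negative binary polarity, per group.

    The yearly negative-attitude trend is this with ``by=("region", "year")``.
    Bilateral instances count as negative via the binary reduction.
    """
    sub = _classified(table, include_neutral)
    if sub.empty:
        return pd.DataFrame(columns=[*by, "n", "negative_pct"])
    grouped = sub.groupby(list(by), observed=True).agg(
        n=("binary", "size"),
        negative=("binary", lambda s: int((s == "negative").sum())),
    )
    grouped["negative_pct"] = (100.0 * grouped["negative"] / grouped["n"]).round(2)
    return grouped.reset_index()[[*by, "n", "negative_pct"]]


def item_share(
    table: pd.DataFrame,
    factor: str,
    polarity_filter: str | None = None,
    year: int | None = None,
    level: str = "keyword",
) -> pd.DataFrame:
    """Percentage share of each item (keyword or subcategory) within a factor.

    Restricts to one factor, optionally to one binary polarity and one year,
    and returns descending shares — the shape of an in-depth "which items
    drive this factor" table.
    """
    known = set(FACTORS)
    if "factor" in table.columns:
        known |= set(table["factor"])
    if factor not in known:
        raise ValueError(f"unknown factor {factor!r}")
    if table.empty:
        return pd.DataFrame(columns=[level, "count", "share_pct"])
    if level not in ("keyword", "subcategory"):
        raise ValueError(f"level must be keyword or subcategory, got {level!r}")
    sub = table[table["factor"] == factor]
    if polarity_filter is not None:
        sub = sub[sub["binary"] == polarity_filter]
    if year is not None:
        sub = sub[sub["year"] == year]
    if sub.empty:
        return pd.DataFrame(columns=[level, "count", "share_pct"])
    counts = sub.groupby(level, observed=True).size().rename("count").reset_index()
    counts["share_pct"] = (100.0 * counts["count"] / counts["count"].sum()).round(2)
    return counts.sort_values(
        ["share_pct", level], ascending=[False, True]
    ).reset_index(drop=True)


def _thread_polarity(labels: Mapping[str, RecommendationLabel], thread: Thread) -> str:
    """Roll up member-message binary labels to a thread-level opinion.

    A thread is *negatively opinionated* iff at least one member message is
    binary-negative and none is binary-positive; symmetric for positive;
    otherwise mixed/neutral.
    """
    binaries = {
        labels[mid].binary for mid in thread.message_ids if mid in labels
    }
    if "negative" in binaries and "positive" not in binaries:
        return "negative"
    if "positive" in binaries and "negative" not in binaries:
        return "positive"
    if binaries - {"excluded"}:
        return "mixed"
    return "neutral"


def _contains_term(text: str, term_norm: str) -> bool:
    norm, _ = normalize_text(text)
    tokens = tokenize(norm)
    n = term_norm.count(" ") + 1
    for i in range(len(tokens) - n + 1):
        if norm[tokens[i].start : tokens[i + n - 1].end] == term_norm:
            return True
    return False


def cooccurrence(
    threads: Iterable[Thread],
    messages: Iterable[Message],
    hospital_mentions: Iterable[HospitalMention],
    labels: Mapping[str, RecommendationLabel],
    term: str,
) -> pd.DataFrame:
    """Term-hospital co-occurrence ratios in negatively opinionated threads.

    For each hospital: ``100 * |negative threads containing term and
    hospital| / |negative threads containing term|``.  Term containment is
    token-boundary matching over thread titles and member-message texts.
    The denominator is recorded in ``DataFrame.attrs["denominator"]``.
    """
    term_norm = normalize_text(term)[0]
    msgs = {m.message_id: m for m in messages}
    hospitals_by_msg: dict[str, set[str]] = {}
    for hm in hospital_mentions:
        if not hm.ambiguous:
            hospitals_by_msg.setdefault(hm.message_id, set()).add(hm.canonical_id)
    neg_with_term: list[set[str]] = []
    for t in threads:
        if _thread_polarity(labels, t) != "negative":
            continue
        has_term = _contains_term(t.title, term_norm) or any(
            mid in msgs and _contains_term(msgs[mid].raw_text, term_norm)
            for mid in t.message_ids
        )
        if not has_term:
            continue
        hosp: set[str] = set()
        for mid in t.message_ids:
            hosp |= hospitals_by_msg.get(mid, set())
        neg_with_term.append(hosp)
    denominator = len(neg_with_term)
    rows = []
    if denominator:
        all_ids = sorted(set().union(*neg_with_term)) if neg_with_term else []
        for cid in all_ids:
            k = sum(1 for hs in neg_with_term if cid in hs)
            rows.append(
                {
                    "term": term,
                    "canonical_id": cid,
                    "threads": k,
                    "cooccurrence_pct": round(100.0 * k / denominator, 2),
                }
            )
    out = pd.DataFrame(rows, columns=["term", "canonical_id", "threads", "cooccurrence_pct"])
    out.attrs["denominator"] = denominator
    out.attrs["definition"] = (
        "percent of negatively opinionated threads containing the term "
        "that also mention the hospital"
    )
    return out


def recommendation_share(n_positive: int | pd.DataFrame, n_total: int | None = None) -> float:
    """Share of positive instances among all four-class instances, in percent.

    Accepts either explicit counts ``(n_positive, n_total)`` or an instance
    table, whose ``polarity`` column supplies them.  Two-decimal rounding.
    """
    if isinstance(n_positive, pd.DataFrame):
        table = n_positive
        total = len(table)
        positive = int((table["polarity"] == "positive").sum())
    else:
        positive, total = n_positive, n_total if n_total is not None else 0
    if total == 0:
        return 0.0
    return round(100.0 * positive / total, 2)
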