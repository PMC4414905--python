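"""End-to-end orchestration: HTML stripping through polarized factor instances.

``run_stages`` is the in-memory engine (pure: same inputs, same outputs);
``run_pipeline`` wraps it with file I/O, writing every intermediate artifact
plus a manifest of per-stage counts, so a run can be audited and re-run
bit-identically.

Stage order: strip HTML -> preprocess -> hospital mention extraction ->
message filtering -> factor detection -> mood-flow classification ->
factor-polarity assignment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import analytics
from .corpus import Message, Thread, read_corpus, strip_html
from .factor_detect import FactorMention, detect_factor_mentions
from .hospital_ner import (
    HospitalMention,
    NerConfig,
    extract_hospital_mentions,
    filter_messages,
)
from .lexicons import (
    FactorLexicon,
    HospitalLexicon,
    SentimentLexicon,
    load_factor_lexicon,
    load_hospital_lexicon,
    load_sentiment_lexicon,
)
from .recommend import (
    PolarizedFactorInstance,
    RecommendationLabel,
    assign_factor_polarity,
    mood_flow_classify,
)

logger = logging.getLogger("hospmine")

__all__ = ["PipelineConfig", "PipelineResult", "run_stages", "run_pipeline"]


@dataclass
class PipelineConfig:
    """File paths plus the tunables of every stage."""

    corpus_path: str = "corpus.jsonl"
    hospitals_path: str = ""
    factors_path: str = ""
    sentiment_path: str = ""
    output_dir: str = "out"
    max_rel_distance: float = 0.25
    max_ngram: int = 5
    negation_window: int = 2
    mood_mode: str = "presence"  # or "last"
    include_titles: bool = False
    include_neutral: bool = False
    use_region: bool = True
    strip_html_first: bool = False

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True),
            encoding="utf-8",
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run."""

    threads: list[Thread]
    messages: list[Message]
    hospital_mentions: list[HospitalMention]
    retained: list[Message]
    factor_mentions: dict[str, list[FactorMention]]
    labels: dict[str, RecommendationLabel]
    instances: list[PolarizedFactorInstance]
    instance_table: pd.DataFrame
    manifest: dict

    @property
    def all_factor_mentions(self) -> list[FactorMention]:
        return [m for ms in self.factor_mentions.values() for m in ms]


def run_stages(
    threads: list[Thread],
    messages: list[Message],
    hospitals: HospitalLexicon,
    factors: FactorLexicon,
    sentiment: SentimentLexicon,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute the detection/classification stages on in-memory objects."""
    config = config or PipelineConfig()
    ner_cfg = NerConfig(
        max_rel_distance=config.max_rel_distance, max_ngram=config.max_ngram
    )
    work = messages
    if config.strip_html_first:
        work = [
            dataclasses.replace(m, raw_text=strip_html(m.raw_text)) for m in messages
        ]
    if config.include_titles:
        first_in_thread = {
            t.message_ids[0]: t.title for t in threads if t.message_ids
        }
        work = [
            dataclasses.replace(
                m, raw_text=f"{first_in_thread[m.message_id]}\n{m.raw_text}"
            )
            if m.message_id in first_in_thread
            else m
            for m in work
        ]

    logger.info("extracting hospital mentions from %d messages", len(work))
    hospital_mentions: list[HospitalMention] = []
    for msg in work:
        hospital_mentions.extend(
            extract_hospital_mentions(msg, hospitals, ner_cfg, use_region=config.use_region)
        )
    retained = filter_messages(work, hospital_mentions)
    logger.info("retained %d/%d messages", len(retained), len(work))

    factor_mentions: dict[str, list[FactorMention]] = {}
    labels: dict[str, RecommendationLabel] = {}
    instances: list[PolarizedFactorInstance] = []
    for msg in retained:
        fm = detect_factor_mentions(msg, factors)
        factor_mentions[msg.message_id] = fm
        label = mood_flow_classify(
            msg, sentiment, negation_window=config.negation_window, mode=config.mood_mode
        )
        labels[msg.message_id] = label
        instances.extend(assign_factor_polarity(fm, label))

    table = analytics.build_instance_table(instances, work, hospital_mentions)
    class_counts = {c: 0 for c in ("positive", "neutral", "bilateral", "negative")}
    for lab in labels.values():
        class_counts[lab.four_class] += 1
    manifest = {
        "config_digest": config.digest(),
        "threads_in": len(threads),
        "messages_in": len(messages),
        "hospital_mentions": len(hospital_mentions),
        "retained": len(retained),
        "factor_mentions": sum(len(v) for v in factor_mentions.values()),
        "instances": len(instances),
        "labels": class_counts,
    }
    return PipelineResult(
        threads=threads,
        messages=work,
        hospital_mentions=hospital_mentions,
        retained=retained,
        factor_mentions=factor_mentions,
        labels=labels,
        instances=instances,
        instance_table=table,
        manifest=manifest,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-to-file run: read corpus and lexicons, write every artifact.

    Writes ``hospital_mentions.tsv``, ``factor_mentions.tsv``, ``labels.tsv``,
    ``instances.csv`` and ``manifest.json`` into ``config.output_dir``.
    """
    threads, messages = read_corpus(config.corpus_path)
    hospitals = load_hospital_lexicon(config.hospitals_path)
    factors = load_factor_lexicon(config.factors_path)
    sentiment = load_sentiment_lexicon(config.sentiment_path)
    result = run_stages(threads, messages, hospitals, factors, sentiment, config)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "message_id": m.message_id,
                "start": m.span[0],
                "end": m.span[1],
                "surface": m.surface,
                "canonical_id": m.canonical_id,
                "step": m.match_step,
                "distance": m.distance,
                "ambiguous": m.ambiguous,
            }
            for m in result.hospital_mentions
        ]
    ).to_csv(out / "hospital_mentions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "message_id": m.message_id,
                "sentence_index": m.sentence_index,
                "start": m.span[0],
                "end": m.span[1],
                "keyword": m.matched_keyword,
                "factor": m.factor,
                "subcategory": m.subcategory,
            }
            for m in result.all_factor_mentions
        ]
    ).to_csv(out / "factor_mentions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "message_id": lab.message_id,
                "four_class": lab.four_class,
                "binary": lab.binary,
                "flow": lab.flow,
            }
            for lab in result.labels.values()
        ]
    ).to_csv(out / "labels.tsv", sep="\t", index=False)
    result.instance_table.to_csv(out / "instances.csv", index=False)
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return result
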