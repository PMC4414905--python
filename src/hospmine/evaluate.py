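"""Precision / recall / F1 scoring against gold labels, per region and averaged.

Metrics are reported as percentages.  Precision is the share of predicted
items that are correct, recall the share of gold items that were found, and
F1 = 2·P·R/(P+R) their harmonic mean.  Per-region rows are complemented by a
macro-average row (arithmetic mean over regions, each region weighted
equally).  Presentation rounding is round-half-up to integer percent.

Match keys per task:

* ``hospital_name`` — (message_id, canonical_id) pairs: a predicted mention
  is correct if the gold says that hospital is mentioned in that message;
* ``factor_detection`` — (message_id, factor) pairs;
* ``recommendation`` — one binary label per message; this task reports
  precision only.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Hashable, Mapping

import pandas as pd

__all__ = [
    "EvalReport",
    "TASKS",
    "precision_recall",
    "f1",
    "round_half_up",
    "evaluate_run",
]

TASKS = ("hospital_name", "factor_detection", "recommendation")


def precision_recall(
    predicted: set[Hashable], gold: set[Hashable]
) -> tuple[float, float]:
    """Precision and recall in percent between two item sets.

    Empty-against-empty scores 100/100 (nothing to find, nothing found
    wrongly); an empty prediction set against nonempty gold scores P = 0.
    """
    tp = len(predicted & gold)
    if not predicted:
        p = 100.0 if not gold else 0.0
    else:
        p = 100.0 * tp / len(predicted)
    if not gold:
        r = 100.0 if not predicted else 0.0
    else:
        r = 100.0 * tp / len(gold)
    return p, r


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall (percent); 0 when both are 0."""
    if not 0 <= p <= 100 or not 0 <= r <= 100:
        raise ValueError(f"P and R must be percentages, got ({p}, {r})")
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (2.5 -> 3), as used for integer-percent display."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EvalReport:
    """Per-region P/R/F1 rows plus a macro-average row, for one task."""

    task: str
    rows: pd.DataFrame  # columns: region, precision, recall, f1 (percent)

    def rounded(self) -> pd.DataFrame:
        """Presentation view: integer percentages (round-half-up)."""
        out = self.rows.copy()
        for col in ("precision", "recall", "f1"):
            if col in out:
                out[col] = out[col].map(
                    lambda v: round_half_up(v) if pd.notna(v) else v
                )
        return out

    @property
    def average(self) -> pd.Series:
        return self.rows[self.rows["region"] == "Average"].iloc[0]


def evaluate_run(
    predictions: Mapping[str, set],
    gold: Mapping[str, set],
    task: str = "hospital_name",
) -> EvalReport:
    """Score predictions against gold, both given as region -> item-key sets.

    Regions present in the gold but absent from predictions are scored with
    an empty prediction set; a region predicted but unknown to the gold is a
    validation error (nothing to score it against).
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; valid: {TASKS}")
    unknown = set(predictions) - set(gold)
    if unknown:
        raise ValueError(f"regions in predictions but not in gold: {sorted(unknown)}")
    rows = []
    for region in gold:
        p, r = precision_recall(set(predictions.get(region, set())), set(gold[region]))
        row = {"region": region, "precision": p}
        if task != "recommendation":
            row["recall"] = r
            row["f1"] = f1(p, r)
        rows.append(row)
    df = pd.DataFrame(rows)
    avg = {"region": "Average"}
    for col in df.columns:
        if col != "region":
            avg[col] = float(df[col].mean())
    df = pd.concat([df, pd.DataFrame([avg])], ignore_index=True)
    return EvalReport(task=task, rows=df)
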