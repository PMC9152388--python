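"""Strict entity-level evaluation: precision, recall and F1.

A predicted mention counts as correct only when its (start, end, type)
triple exactly equals a gold mention in the same sentence.  Micro-averaged
precision is correct/predicted and recall is correct/gold (conventions:
0 when the denominator is 0); per-type rows apply the same rule restricted
to one entity type.  Near-misses are tallied for error analysis: a predicted
span that overlaps a gold span but differs in extent is a *boundary error*;
an exact span with the wrong type is a *type error*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .tagging import EntityMention, LabeledSentence, TagSchema, DEFAULT_SCHEMA


class EvaluationError(ValueError):
    pass


@dataclass
class TypeCounts:
    gold: int = 0
    predicted: int = 0
    correct: int = 0
    boundary_errors: int = 0
    type_errors: int = 0

    @property
    def precision(self) -> float:
        return 100.0 * self.correct / self.predicted if self.predicted else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.correct / self.gold if self.gold else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2.0 * p * r / (p + r) if p + r > 0 else 0.0


@dataclass
class EvalResult:
    per_type: dict[str, TypeCounts]
    average: str = "micro"

    @property
    def overall(self) -> TypeCounts:
        total = TypeCounts()
        for c in self.per_type.values():
            total.gold += c.gold
            total.predicted += c.predicted
            total.correct += c.correct
            total.boundary_errors += c.boundary_errors
            total.type_errors += c.type_errors
        return total

    @property
    def precision(self) -> float:
        if self.average == "macro":
            rows = list(self.per_type.values())
            return sum(c.precision for c in rows) / len(rows) if rows else 0.0
        return self.overall.precision

    @property
    def recall(self) -> float:
        if self.average == "macro":
            rows = list(self.per_type.values())
            return sum(c.recall for c in rows) / len(rows) if rows else 0.0
        return self.overall.recall

    @property
    def f1(self) -> float:
        if self.average == "macro":
            rows = list(self.per_type.values())
            return sum(c.f1 for c in rows) / len(rows) if rows else 0.0
        return self.overall.f1


def _as_mentions(item) -> list[EntityMention]:
    if isinstance(item, LabeledSentence):
        return item.mentions()
    return [EntityMention(*m) for m in item]


def strict_match_eval(
    gold: Sequence,
    pred: Sequence,
    schema: TagSchema = DEFAULT_SCHEMA,
    average: str = "micro",
) -> EvalResult:
    """Evaluate sentence-aligned gold and predicted mention sets.

    Each element of ``gold``/``pred`` is a :class:`LabeledSentence` or an
    iterable of ``(start, end, type)`` triples.  Duplicate predicted mentions
    within a sentence are deduplicated before matching.
    """
    if len(gold) != len(pred):
        raise EvaluationError(
            f"sentence count mismatch: {len(gold)} gold vs {len(pred)} predicted"
        )
    if average not in ("micro", "macro"):
        raise ValueError(f"unknown average {average!r}")
    counts = {t: TypeCounts() for t in schema.types}
    for gold_item, pred_item in zip(gold, pred):
        g = set(_as_mentions(gold_item))
        p = set(_as_mentions(pred_item))
        for m in g:
            counts[m.type].gold += 1
        for m in p:
            counts[m.type].predicted += 1
            if m in g:
                counts[m.type].correct += 1
            elif any(x.start == m.start and x.end == m.end for x in g):
                counts[m.type].type_errors += 1
            elif any(x.start < m.end and m.start < x.end for x in g):
                counts[m.type].boundary_errors += 1
    return EvalResult(per_type=counts, average=average)


def per_type_report(result: EvalResult) -> str:
    """Aligned text table: one row per entity type plus an overall row."""
    header = (
        f"{'type':<8}{'gold':>6}{'pred':>6}{'corr':>6}"
        f"{'P%':>8}{'R%':>8}{'F1%':>8}{'bnd':>5}{'typ':>5}"
    )
    lines = [header]
    rows = list(result.per_type.items()) + [("ALL", result.overall)]
    for name, c in rows:
        lines.append(
            f"{name:<8}{c.gold:>6}{c.predicted:>6}{c.correct:>6}"
            f"{c.precision:>8.2f}{c.recall:>8.2f}{c.f1:>8.2f}"
            f"{c.boundary_errors:>5}{c.type_errors:>5}"
        )
    return "\n".join(lines)


def report_rows(result: EvalResult) -> list[dict]:
    """Machine-readable rows mirroring :func:`per_type_report`."""
    rows = []
    for name, c in list(result.per_type.items()) + [("ALL", result.overall)]:
        rows.append(
            {
                "type": name,
                "gold": c.gold,
                "predicted": c.predicted,
                "correct": c.correct,
                "precision": round(c.precision, 2),
                "recall": round(c.recall, 2),
                "f1": round(c.f1, 2),
                "boundary_errors": c.boundary_errors,
                "type_errors": c.type_errors,
            }
        )
    return rows
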