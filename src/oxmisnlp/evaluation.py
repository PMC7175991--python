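"""Span-level extraction evaluation: correct/spurious/missed counts and P/R/F1.

Predicted spans are matched one-to-one against gold annotations per concept
label, greedily in gold start-offset order.  Counts follow the standard NER
bookkeeping: *correct* (true positive), *spurious* (false positive),
*missed* (false negative, always ``annotated - correct``).  Precision,
recall and F1 are computed per concept and micro-averaged by pooling raw
counts across concepts before dividing — the convention under which a
single headline P/R/F1 triple summarises a multi-concept extractor.

Negation and experiencer attributes are ignored for matching: this is a
span-identification evaluation (label + position only).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .corpus import AnnotationSpan, ConceptLabel


class MatchMode(str, Enum):
    EXACT = "exact"
    LENIENT_OVERLAP = "lenient_overlap"


@dataclass(frozen=True)
class MatchPolicy:
    """How a predicted span may count as correct for a gold span.

    ``exact`` requires identical offsets; ``lenient_overlap`` (default, the
    usual lenient criterion in NER toolkits) accepts any character overlap.
    The label must always agree.
    """

    mode: MatchMode = MatchMode.LENIENT_OVERLAP

    def matches(self, gold: AnnotationSpan, pred: AnnotationSpan) -> bool:
        if gold.label != pred.label or gold.doc_id != pred.doc_id:
            return False
        if self.mode is MatchMode.EXACT:
            return gold.start == pred.start and gold.end == pred.end
        return gold.start < pred.end and pred.start < gold.end


@dataclass(frozen=True)
class ConceptCounts:
    """Evaluation counts for one concept label."""

    label: Optional[ConceptLabel]
    annotated: int
    correct: int
    spurious: int

    def __post_init__(self) -> None:
        if min(self.annotated, self.correct, self.spurious) < 0:
            raise ValueError("counts must be non-negative")
        if self.correct > self.annotated:
            raise ValueError(
                f"correct ({self.correct}) exceeds annotated ({self.annotated})"
            )

    @property
    def missed(self) -> int:
        return self.annotated - self.correct


@dataclass(frozen=True)
class MetricRow:
    precision: float
    recall: float
    f1: float

    def rounded(self, ndigits: int = 2) -> "MetricRow":
        """Half-up rounding for presentation; internal values stay exact."""
        return MetricRow(
            _round_half_up(self.precision, ndigits),
            _round_half_up(self.recall, ndigits),
            _round_half_up(self.f1, ndigits),
        )


def _round_half_up(x: float, ndigits: int) -> float:
    scale = 10**ndigits
    return int(x * scale + 0.5) / scale


def metrics(counts: ConceptCounts) -> MetricRow:
    """Precision, recall and F1 from raw counts.

    precision = correct / (correct + spurious); recall = correct /
    annotated; f1 = 2PR/(P+R).  Zero denominators yield 0 by convention.
    """
    extracted = counts.correct + counts.spurious
    precision = counts.correct / extracted if extracted else 0.0
    recall = counts.correct / counts.annotated if counts.annotated else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return MetricRow(precision, recall, f1)


def micro_average(rows: Sequence[ConceptCounts]) -> MetricRow:
    """Pool counts across concepts, then compute a single metric triple."""
    if not rows:
        raise ValueError("micro_average requires at least one count row")
    pooled = ConceptCounts(
        label=None,
        annotated=sum(r.annotated for r in rows),
        correct=sum(r.correct for r in rows),
        spurious=sum(r.spurious for r in rows),
    )
    return metrics(pooled)


def pooled_counts(rows: Sequence[ConceptCounts]) -> ConceptCounts:
    return ConceptCounts(
        label=None,
        annotated=sum(r.annotated for r in rows),
        correct=sum(r.correct for r in rows),
        spurious=sum(r.spurious for r in rows),
    )


def match_spans(
    gold: Iterable[AnnotationSpan],
    predicted: Iterable[AnnotationSpan],
    policy: MatchPolicy = MatchPolicy(),
    known_doc_ids: Optional[set[str]] = None,
) -> dict[ConceptLabel, ConceptCounts]:
    """One-to-one greedy matching of predictions to gold, per concept.

    Gold spans are visited in (doc_id, start) order; each takes the first
    compatible unused prediction, ties broken toward the longest predicted
    span (then earliest start).  Guarantees, per label:
    ``correct + spurious == n_predicted`` and ``correct + missed == n_gold``.
    """
    gold = list(gold)
    predicted = list(predicted)
    if known_doc_ids is not None:
        for span in [*gold, *predicted]:
            if span.doc_id not in known_doc_ids:
                raise ValueError(f"span references unknown document {span.doc_id!r}")

    counts: dict[ConceptLabel, ConceptCounts] = {}
    for label in ConceptLabel:
        g = sorted(
            (s for s in gold if s.label == label), key=lambda s: (s.doc_id, s.start)
        )
        p = [s for s in predicted if s.label == label]
        used = [False] * len(p)
        correct = 0
        for gspan in g:
            candidates = [
                (-(p[i].end - p[i].start), p[i].start, i)
                for i in range(len(p))
                if not used[i] and policy.matches(gspan, p[i])
            ]
            if candidates:
                _, _, i = min(candidates)
                used[i] = True
                correct += 1
        counts[label] = ConceptCounts(
            label=label,
            annotated=len(g),
            correct=correct,
            spurious=len(p) - correct,
        )
    return counts


REPORT_COLUMNS = (
    "label",
    "annotated",
    "correct",
    "spurious",
    "missed",
    "precision",
    "recall",
    "f1",
)


def evaluation_report(
    per_label: dict[ConceptLabel, ConceptCounts],
    path: Optional[Union[str, Path]] = None,
) -> str:
    """Render the per-concept table plus a pooled micro-average row as CSV.

    Metric cells are rounded half-up to 2 decimals, matching how such
    tables are conventionally printed; raw counts are exact.  Returns the
    CSV text and optionally writes it to ``path``.
    """
    rows = [per_label[label] for label in ConceptLabel if label in per_label]
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(REPORT_COLUMNS)
    for counts in rows:
        m = metrics(counts).rounded()
        writer.writerow(
            [
                counts.label.value,
                counts.annotated,
                counts.correct,
                counts.spurious,
                counts.missed,
                f"{m.precision:.2f}",
                f"{m.recall:.2f}",
                f"{m.f1:.2f}",
            ]
        )
    if rows:
        pooled = pooled_counts(rows)
        m = micro_average(rows).rounded()
        writer.writerow(
            [
                "micro_average",
                pooled.annotated,
                pooled.correct,
                pooled.spurious,
                pooled.missed,
                f"{m.precision:.2f}",
                f"{m.recall:.2f}",
                f"{m.f1:.2f}",
            ]
        )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
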