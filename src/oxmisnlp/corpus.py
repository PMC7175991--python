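"""Core corpus data model and standoff annotation I/O.

A corpus is a set of clinical documents plus character-offset annotations
("spans") labelled with one of eight risk-factor concepts.  Annotations are
stored standoff-style: the text is never modified, spans reference it by
0-based half-open ``[start, end)`` character offsets.

The on-disk format is JSON-lines: one record per line, document records
first, then span records.  It is diffable, language-neutral and round-trips
byte-identically once canonicalised.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Union


class ConceptLabel(str, Enum):
    """The closed set of eight free-text risk-factor concepts.

    Together they cover the nine free-text predictors of the 17-item OxMIS
    model; ``MEDICATION`` covers two (recent antipsychotic and recent
    antidepressant treatment), split downstream by glossary lookup.
    """

    VIOLENCE = "violence"
    SELF_HARM = "self_harm"
    EDUCATION = "education"
    MEDICATION = "medication"
    BENEFITS = "benefits"
    SUBSTANCE_USE_DISORDER = "substance_use_disorder"
    SUICIDE = "suicide"
    PSYCHIATRIC_ADMISSION = "psychiatric_admission"


class Experiencer(str, Enum):
    """Who a clinical mention refers to."""

    PATIENT = "patient"
    PARENT = "parent"
    OTHER = "other"


class DocKind(str, Enum):
    NOTE = "note"
    CORRESPONDENCE = "correspondence"


class CorpusError(ValueError):
    """Raised on malformed standoff records or invariant violations."""


@dataclass(frozen=True)
class Document:
    """One clinical document: a free-text note or a piece of correspondence."""

    doc_id: str
    patient_id: str
    date: _dt.date
    kind: DocKind
    text: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusError("doc_id must be non-empty")


@dataclass(frozen=True)
class AnnotationSpan:
    """A labelled text span with negation and experiencer attributes.

    ``raw_text`` caches the document slice so that spans remain
    interpretable away from their document; validity against the document is
    checked by :meth:`Corpus.validate`.
    """

    doc_id: str
    start: int
    end: int
    label: ConceptLabel
    negated: bool = False
    experiencer: Experiencer = Experiencer.PATIENT
    raw_text: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(
                f"span offsets must satisfy 0 <= start < end, got "
                f"[{self.start}, {self.end}) in doc {self.doc_id!r}"
            )

    @property
    def identity(self) -> tuple[str, int, int, ConceptLabel]:
        return (self.doc_id, self.start, self.end, self.label)


@dataclass
class Corpus:
    """Documents plus their gold-standard annotation spans."""

    documents: list[Document] = field(default_factory=list)
    gold: list[AnnotationSpan] = field(default_factory=list)

    def doc_index(self) -> dict[str, Document]:
        return {d.doc_id: d for d in self.documents}

    def spans_for(self, doc_id: str) -> list[AnnotationSpan]:
        return [s for s in self.gold if s.doc_id == doc_id]

    def validate(self) -> None:
        """Check all corpus invariants; raise :class:`CorpusError` on failure."""
        index: dict[str, Document] = {}
        for doc in self.documents:
            if doc.doc_id in index:
                raise CorpusError(f"duplicate doc_id {doc.doc_id!r}")
            index[doc.doc_id] = doc
        seen: set[tuple[str, int, int, ConceptLabel]] = set()
        for span in self.gold:
            doc = index.get(span.doc_id)
            if doc is None:
                raise CorpusError(f"span references unknown doc_id {span.doc_id!r}")
            if span.end > len(doc.text):
                raise CorpusError(
                    f"span [{span.start}, {span.end}) exceeds length of doc "
                    f"{span.doc_id!r} ({len(doc.text)} chars)"
                )
            slice_ = doc.text[span.start : span.end]
            if span.raw_text and span.raw_text != slice_:
                raise CorpusError(
                    f"span raw_text {span.raw_text!r} != document slice "
                    f"{slice_!r} at [{span.start}, {span.end}) in {span.doc_id!r}"
                )
            if span.identity in seen:
                raise CorpusError(
                    f"duplicate gold span {span.identity} (same start/end/label)"
                )
            seen.add(span.identity)

    def with_filled_raw_text(self) -> "Corpus":
        """Return a copy whose spans all carry their document slice."""
        index = self.doc_index()
        gold = [
            s
            if s.raw_text
            else replace(s, raw_text=index[s.doc_id].text[s.start : s.end])
            for s in self.gold
        ]
        return Corpus(documents=list(self.documents), gold=gold)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return (
            self.documents == other.documents
            and self.with_filled_raw_text().gold == other.with_filled_raw_text().gold
        )


def _doc_record(doc: Document) -> dict:
    return {
        "type": "doc",
        "doc_id": doc.doc_id,
        "patient_id": doc.patient_id,
        "date": doc.date.isoformat(),
        "kind": doc.kind.value,
        "text": doc.text,
    }


def _span_record(span: AnnotationSpan) -> dict:
    return {
        "type": "span",
        "doc_id": span.doc_id,
        "start": span.start,
        "end": span.end,
        "label": span.label.value,
        "negated": span.negated,
        "experiencer": span.experiencer.value,
    }


def write_standoff(corpus: Corpus, path: Union[str, Path]) -> None:
    """Serialise a corpus to a JSON-lines standoff file.

    Documents are written before spans, each in corpus order, one compact
    JSON object per line.  ``write -> read -> write`` is byte-identical.
    """
    corpus.validate()
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            fh.write(json.dumps(_doc_record(doc), ensure_ascii=False) + "\n")
        for span in corpus.gold:
            fh.write(json.dumps(_span_record(span), ensure_ascii=False) + "\n")


def read_standoff(path: Union[str, Path]) -> Corpus:
    """Read a JSON-lines standoff file into a validated :class:`Corpus`.

    Span records may omit ``negated`` and ``experiencer``; they default to
    the modal annotation (affirmed, patient-experienced).  Raises
    :class:`CorpusError` naming the offending line on malformed input and
    the offending span on invariant violations.
    """
    path = Path(path)
    documents: list[Document] = []
    spans: list[AnnotationSpan] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: invalid JSON ({exc})") from exc
            rtype = record.get("type")
            try:
                if rtype == "doc":
                    documents.append(
                        Document(
                            doc_id=record["doc_id"],
                            patient_id=record["patient_id"],
                            date=_dt.date.fromisoformat(record["date"]),
                            kind=DocKind(record["kind"]),
                            text=record["text"],
                        )
                    )
                elif rtype == "span":
                    spans.append(
                        AnnotationSpan(
                            doc_id=record["doc_id"],
                            start=int(record["start"]),
                            end=int(record["end"]),
                            label=ConceptLabel(record["label"]),
                            negated=bool(record.get("negated", False)),
                            experiencer=Experiencer(
                                record.get("experiencer", "patient")
                            ),
                        )
                    )
                else:
                    raise CorpusError(
                        f"line {lineno}: unknown record type {rtype!r}"
                    )
            except (KeyError, ValueError) as exc:
                if isinstance(exc, CorpusError):
                    raise
                raise CorpusError(f"line {lineno}: malformed record ({exc})") from exc
    corpus = Corpus(documents=documents, gold=spans).with_filled_raw_text()
    corpus.validate()
    return corpus


def concept_span_counts(spans: Iterable[AnnotationSpan]) -> dict[ConceptLabel, int]:
    """Per-concept span tally (the shape of an annotation-summary table)."""
    counts = {label: 0 for label in ConceptLabel}
    for span in spans:
        counts[span.label] += 1
    return counts
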