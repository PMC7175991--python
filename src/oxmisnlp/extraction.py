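"""Concept extraction: BIO sequence labelling plus rule-based attributes.

The extractor tags document tokens with BIO-encoded concept labels using
an averaged-perceptron tagger, decodes contiguous tag runs back into
character-offset spans, and then resolves two attributes per span with
rules that are pure functions of the containing sentence:

* negation — NegEx-style trigger search: a span is negated when a
  pre-trigger phrase occurs within a token window before it (or a
  post-trigger after it) inside the same sentence, unless the trigger
  occurrence is part of a pseudo-trigger phrase ("no increase in").
* experiencer — who the mention is about: ``parent`` when a parental term
  precedes the span in its sentence, ``other`` for non-parent third
  parties, ``patient`` otherwise.

Medication-group resolution (antipsychotic / antidepressant / other) is a
separate glossary lookup applied where the predictor mapping needs it; the
extraction schema keeps a single combined medication concept.

Training happens in two phases: phase 1 on a gold-annotated corpus, phase
2 ("fine-tuning") on accept/reject judgments of the model's own output —
accepted spans become additional gold supervision, rejected spans become
explicit O-labelled (outside) regions, and all unjudged tokens are left
unsupervised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .corpus import (
    AnnotationSpan,
    ConceptLabel,
    Corpus,
    CorpusError,
    Document,
    Experiencer,
)
from .lexicons import (
    DEFAULT_NEGATION_LEXICON,
    OTHER_PERSON_TERMS,
    PARENT_TERMS,
    NegationLexicon,
)
from .tagger import AveragedPerceptron, TaggedSequence, tag_sequence, train_tagger
from .text import Token, sentence_containing, tokenize, tokens_in

MODEL_FORMAT_VERSION = 1

BIO_TAGS = ["O"] + [
    f"{prefix}-{label.value}" for label in ConceptLabel for prefix in ("B", "I")
]


@dataclass
class TrainConfig:
    epochs: int = 6
    fine_tune_epochs: int = 3


@dataclass
class ExtractorModel:
    """Trained extractor state plus training metadata."""

    tagger: AveragedPerceptron
    seed: int
    n_training_spans: int
    phase: int = 1
    negation: NegationLexicon = field(default=DEFAULT_NEGATION_LEXICON)

    def save(self, path: Union[str, Path]) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "seed": self.seed,
            "n_training_spans": self.n_training_spans,
            "phase": self.phase,
            "negation": {
                "pre_triggers": list(self.negation.pre_triggers),
                "post_triggers": list(self.negation.post_triggers),
                "pseudo_triggers": list(self.negation.pseudo_triggers),
                "scope_window": self.negation.scope_window,
            },
            "tagger": self.tagger.to_dict(),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ExtractorModel":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        if data.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format {data.get('format_version')!r}"
            )
        return cls(
            tagger=AveragedPerceptron.from_dict(data["tagger"]),
            seed=data["seed"],
            n_training_spans=data["n_training_spans"],
            phase=data["phase"],
            negation=NegationLexicon(
                pre_triggers=tuple(data["negation"]["pre_triggers"]),
                post_triggers=tuple(data["negation"]["post_triggers"]),
                pseudo_triggers=tuple(data["negation"]["pseudo_triggers"]),
                scope_window=data["negation"]["scope_window"],
            ),
        )


def spans_to_bio(
    tokens: Sequence[Token], spans: Sequence[AnnotationSpan]
) -> list[Optional[str]]:
    """BIO tag per token; spans win over O, first span wins overlaps."""
    tags: list[Optional[str]] = ["O"] * len(tokens)
    for span in sorted(spans, key=lambda s: (s.start, s.end)):
        indices = tokens_in(list(tokens), span.start, span.end)
        for pos, i in enumerate(indices):
            if tags[i] != "O":
                continue
            prefix = "B" if pos == 0 else "I"
            tags[i] = f"{prefix}-{span.label.value}"
    return tags


def bio_to_spans(
    doc: Document, tokens: Sequence[Token], tags: Sequence[str]
) -> list[AnnotationSpan]:
    """Decode contiguous B/I runs into character-offset spans."""
    spans: list[AnnotationSpan] = []
    i = 0
    while i < len(tags):
        tag = tags[i]
        if tag == "O":
            i += 1
            continue
        label = ConceptLabel(tag.split("-", 1)[1])
        start_tok = i
        i += 1
        while i < len(tags) and tags[i] == f"I-{label.value}":
            i += 1
        start = tokens[start_tok].start
        end = tokens[i - 1].end
        spans.append(
            AnnotationSpan(
                doc_id=doc.doc_id,
                start=start,
                end=end,
                label=label,
                raw_text=doc.text[start:end],
            )
        )
    return spans


def _corpus_sequences(corpus: Corpus) -> list[TaggedSequence]:
    sequences = []
    for doc in corpus.documents:
        tokens = tokenize(doc.text)
        if not tokens:
            continue
        tags = spans_to_bio(tokens, corpus.spans_for(doc.doc_id))
        sequences.append(([t.text for t in tokens], tags))
    return sequences


def train(
    corpus: Corpus,
    seed: int = 0,
    config: TrainConfig = TrainConfig(),
    negation: NegationLexicon = DEFAULT_NEGATION_LEXICON,
) -> ExtractorModel:
    """Phase-1 training on a gold-annotated corpus.

    Deterministic given seed and corpus.  Raises on an empty corpus.
    """
    corpus.validate()
    if not corpus.documents:
        raise ValueError("cannot train on an empty corpus")
    tagger = AveragedPerceptron(tags=BIO_TAGS)
    train_tagger(tagger, _corpus_sequences(corpus), config.epochs, seed)
    return ExtractorModel(
        tagger=tagger,
        seed=seed,
        n_training_spans=len(corpus.gold),
        phase=1,
        negation=negation,
    )


def fine_tune(
    model: ExtractorModel,
    judgments: Sequence[tuple[AnnotationSpan, bool]],
    docs: Sequence[Document],
    seed: int = 0,
    config: TrainConfig = TrainConfig(),
) -> ExtractorModel:
    """Phase-2 refinement from accept/reject review of model output.

    Accepted spans supervise their tokens with the span's BIO tags;
    rejected spans supervise theirs with O; all other tokens carry no
    supervision.  An empty judgment list returns the model unchanged (same
    predictions, phase bumped to 2).
    """
    index = {d.doc_id: d for d in docs}
    for span, _ in judgments:
        if span.doc_id not in index:
            raise CorpusError(
                f"judgment span references unknown document {span.doc_id!r}"
            )
    tagger = AveragedPerceptron.from_dict(model.tagger.to_dict())
    if judgments:
        by_doc: dict[str, list[tuple[AnnotationSpan, bool]]] = {}
        for span, accept in judgments:
            by_doc.setdefault(span.doc_id, []).append((span, accept))
        sequences: list[TaggedSequence] = []
        for doc_id, judged in sorted(by_doc.items()):
            doc = index[doc_id]
            tokens = tokenize(doc.text)
            tags: list[Optional[str]] = [None] * len(tokens)
            accepted = [s for s, ok in judged if ok]
            rejected = [s for s, ok in judged if not ok]
            for span in rejected:
                for i in tokens_in(tokens, span.start, span.end):
                    tags[i] = "O"
            bio = spans_to_bio(tokens, accepted)
            for span in accepted:
                for i in tokens_in(tokens, span.start, span.end):
                    tags[i] = bio[i]
            sequences.append(([t.text for t in tokens], tags))
        train_tagger(tagger, sequences, config.fine_tune_epochs, seed)
    n_accepted = sum(1 for _, ok in judgments if ok)
    return ExtractorModel(
        tagger=tagger,
        seed=seed,
        n_training_spans=model.n_training_spans + n_accepted,
        phase=2,
        negation=model.negation,
    )


def detect_negation(
    doc: Document,
    span: AnnotationSpan,
    lexicon: NegationLexicon = DEFAULT_NEGATION_LEXICON,
) -> bool:
    """NegEx-style negation test for one span.

    True iff a pre-trigger phrase ends within ``scope_window`` tokens
    before the span (or a post-trigger begins within the window after it)
    in the same sentence, and that trigger occurrence is not part of a
    pseudo-trigger phrase.
    """
    s, e = sentence_containing(doc.text, span.start, span.end)
    sent_tokens = tokenize(doc.text[s:e])
    words = [t.lower for t in sent_tokens]
    span_idx = tokens_in(sent_tokens, span.start - s, span.end - s)
    if not span_idx:
        return False
    first, last = span_idx[0], span_idx[-1]
    pseudo = _phrase_occurrences(words, lexicon.pseudo_triggers)

    for trig_start, trig_end in _phrase_occurrences(words, lexicon.pre_triggers):
        # distance = token steps from the trigger's last token to the span
        if trig_end <= first and first - (trig_end - 1) <= lexicon.scope_window:
            if not _inside_any(trig_start, trig_end, pseudo):
                return True
    for trig_start, trig_end in _phrase_occurrences(words, lexicon.post_triggers):
        if trig_start > last and trig_start - last <= lexicon.scope_window:
            if not _inside_any(trig_start, trig_end, pseudo):
                return True
    return False


def _phrase_occurrences(
    words: Sequence[str], phrases: Sequence[str]
) -> list[tuple[int, int]]:
    """Token ranges [start, end) where any of the phrases occurs."""
    occurrences = []
    split_phrases = [p.lower().split() for p in phrases]
    for phrase in split_phrases:
        n = len(phrase)
        for i in range(len(words) - n + 1):
            if list(words[i : i + n]) == phrase:
                occurrences.append((i, i + n))
    return occurrences


def _inside_any(start: int, end: int, ranges: Sequence[tuple[int, int]]) -> bool:
    return any(rs <= start and end <= re for rs, re in ranges)


def attribute_experiencer(
    doc: Document,
    span: AnnotationSpan,
    parent_terms: Sequence[str] = PARENT_TERMS,
    other_terms: Sequence[str] = OTHER_PERSON_TERMS,
) -> Experiencer:
    """Who the mention refers to, from family terms earlier in the sentence."""
    s, e = sentence_containing(doc.text, span.start, span.end)
    sent_tokens = tokenize(doc.text[s:e])
    span_idx = tokens_in(sent_tokens, span.start - s, span.end - s)
    first = span_idx[0] if span_idx else len(sent_tokens)
    preceding = {t.lower for t in sent_tokens[:first]}
    if preceding & set(parent_terms):
        return Experiencer.PARENT
    if preceding & set(other_terms):
        return Experiencer.OTHER
    return Experiencer.PATIENT


def predict(
    model: ExtractorModel,
    doc: Document,
    resolve_attributes: bool = True,
) -> list[AnnotationSpan]:
    """Extract concept spans from one document.

    Emits only labels from the closed eight-concept set (guaranteed by the
    BIO tag inventory).  With ``resolve_attributes`` (default), negation
    and experiencer are filled in by the rule-based passes.
    """
    tokens = tokenize(doc.text)
    if not tokens:
        return []
    tags = tag_sequence(model.tagger, [t.text for t in tokens])
    spans = bio_to_spans(doc, tokens, tags)
    if not resolve_attributes:
        return spans
    resolved = []
    for span in spans:
        negated = detect_negation(doc, span, model.negation)
        experiencer = attribute_experiencer(doc, span)
        resolved.append(
            AnnotationSpan(
                doc_id=span.doc_id,
                start=span.start,
                end=span.end,
                label=span.label,
                negated=negated,
                experiencer=experiencer,
                raw_text=span.raw_text,
            )
        )
    return resolved


def predict_corpus(model: ExtractorModel, corpus: Corpus) -> list[AnnotationSpan]:
    spans: list[AnnotationSpan] = []
    for doc in corpus.documents:
        spans.extend(predict(model, doc))
    return spans
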