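"""Assemble the 17 OxMIS predictor variables per patient.

Eight predictors come verbatim from structured record fields (age, sex,
drug abuse, alcohol abuse, current episode, length of first stay, number of
previous episodes, comorbid depression).  The remaining nine are derived
from extracted free-text mentions turned into dated evidence events:
previous violent crime, previous self-harm, recent antipsychotic treatment,
recent antidepressant treatment, benefits receipt, highest education, and
the three parental variables (psychiatric admission, drug/alcohol use
disorder, suicide).

Historical predictors use carry-forward: one affirmed mention at any time
on or before the reference date sets the variable true for all later
time-points.  The two medication predictors are recency-bound (treatment in
the last six months).  Parental variables support an absence-inference
rule: when the notes contain an extensive family history that never
mentions them, they are assumed absent rather than unknown.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .corpus import AnnotationSpan, ConceptLabel, Document, Experiencer
from .lexicons import FAMILY_TERMS, MedicationGlossary, DEFAULT_MEDICATION_GLOSSARY
from .text import sentence_spans, word_tokens


class Missing(Enum):
    """Sentinel for a predictor with no usable evidence."""

    MISSING = "MISSING"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"


MISSING = Missing.MISSING

TriState = Union[bool, Missing]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class EpisodeType(str, Enum):
    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"


class EducationLevel(str, Enum):
    SECONDARY = "secondary"
    UPPER_SECONDARY = "upper_secondary"
    POST_SECONDARY = "post_secondary"


EDUCATION_ORDER = {
    EducationLevel.SECONDARY: 0,
    EducationLevel.UPPER_SECONDARY: 1,
    EducationLevel.POST_SECONDARY: 2,
}

# the nine predictors whose evidence comes from free text
FREE_TEXT_PREDICTORS = (
    "violent_crime",
    "self_harm",
    "antipsychotic_recent",
    "antidepressant_recent",
    "benefits",
    "education",
    "parental_psych_admission",
    "parental_substance_disorder",
    "parental_suicide",
)

HISTORICAL_PREDICTORS = (
    "violent_crime",
    "self_harm",
    "benefits",
    "parental_psych_admission",
    "parental_substance_disorder",
    "parental_suicide",
)

RECENCY_PREDICTORS = ("antipsychotic_recent", "antidepressant_recent")

PARENTAL_PREDICTORS = (
    "parental_psych_admission",
    "parental_substance_disorder",
    "parental_suicide",
)


@dataclass(frozen=True)
class StructuredRecord:
    """The eight structured-field predictors plus identifiers."""

    patient_id: str
    sex: Sex
    age: float
    diagnosis: str
    current_episode: EpisodeType
    first_stay_gt7days: bool
    previous_episodes_gt7: bool
    drug_abuse: bool
    alcohol_abuse: bool
    comorbid_depression: bool


@dataclass
class OxMISVariables:
    """The 17-predictor vector for one patient at a reference date.

    Tri-state fields are ``True``/``False``/``MISSING``; education is a
    three-level ordinal or ``MISSING``.  Structured-source fields are never
    missing when a structured record was supplied.
    """

    patient_id: str
    age: float
    sex: Sex
    current_episode: EpisodeType
    first_stay_gt7days: bool
    previous_episodes_gt7: bool
    drug_abuse: bool
    alcohol_abuse: bool
    comorbid_depression: bool
    violent_crime: TriState = MISSING
    self_harm: TriState = MISSING
    antipsychotic_recent: TriState = MISSING
    antidepressant_recent: TriState = MISSING
    benefits: TriState = MISSING
    education: Union[EducationLevel, Missing] = MISSING
    parental_psych_admission: TriState = MISSING
    parental_substance_disorder: TriState = MISSING
    parental_suicide: TriState = MISSING

    PREDICTORS = (
        "age",
        "sex",
        "current_episode",
        "first_stay_gt7days",
        "previous_episodes_gt7",
        "drug_abuse",
        "alcohol_abuse",
        "comorbid_depression",
    ) + FREE_TEXT_PREDICTORS

    def as_completion(self, overrides: dict) -> dict:
        """Constructor kwargs with MISSING slots filled from ``overrides``."""
        kwargs = {"patient_id": self.patient_id}
        for name in self.PREDICTORS:
            kwargs[name] = overrides.get(name, getattr(self, name))
        return kwargs

    def missing_predictors(self) -> list[str]:
        return [
            name for name in self.PREDICTORS if getattr(self, name) is MISSING
        ]

    def as_dict(self) -> dict:
        out = {}
        for name in ("patient_id",) + self.PREDICTORS:
            value = getattr(self, name)
            if value is MISSING:
                out[name] = ""
            elif isinstance(value, Enum):
                out[name] = value.value
            else:
                out[name] = value
        return out


class Polarity(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"


class EventSource(str, Enum):
    STRUCTURED = "structured"
    EXTRACTED = "extracted"


@dataclass(frozen=True)
class EvidenceEvent:
    """One dated piece of evidence about one predictor.

    ``value`` carries a categorical payload where the predictor needs one
    (an :class:`EducationLevel` for education); extracted education spans
    carry ``None`` because level sub-categorisation is outside the current
    extraction schema, so education resolves only from events that state a
    level explicitly.
    """

    patient_id: str
    date: _dt.date
    variable: str
    polarity: Polarity
    source: EventSource
    provenance: str = ""
    value: Optional[EducationLevel] = None


def _concept_to_variable(
    label: ConceptLabel, experiencer: Experiencer, med_group: str = ""
) -> Optional[str]:
    """Mapping from (concept, experiencer[, medication group]) to predictor.

    Mentions with no rule (e.g. a sibling's substance use, an 'other'-group
    medication) produce no event.
    """
    if label is ConceptLabel.MEDICATION:
        if experiencer is not Experiencer.PATIENT:
            return None
        return {
            "antipsychotic": "antipsychotic_recent",
            "antidepressant": "antidepressant_recent",
            "other": None,
        }[med_group]
    if label is ConceptLabel.SUICIDE:
        return "parental_suicide" if experiencer is Experiencer.PARENT else None
    if label is ConceptLabel.SUBSTANCE_USE_DISORDER:
        if experiencer is Experiencer.PARENT:
            return "parental_substance_disorder"
        return None  # the patient's own disorder is a structured-field item
    if label is ConceptLabel.PSYCHIATRIC_ADMISSION:
        if experiencer is Experiencer.PARENT:
            return "parental_psych_admission"
        return None  # patient admissions are covered by structured episodes
    if experiencer is not Experiencer.PATIENT:
        return None
    return {
        ConceptLabel.VIOLENCE: "violent_crime",
        ConceptLabel.SELF_HARM: "self_harm",
        ConceptLabel.BENEFITS: "benefits",
        ConceptLabel.EDUCATION: "education",
    }[label]


def spans_to_events(
    spans: Iterable[AnnotationSpan],
    docs: Sequence[Document],
    glossary: MedicationGlossary = DEFAULT_MEDICATION_GLOSSARY,
) -> list[EvidenceEvent]:
    """Turn post-processed spans into dated per-predictor evidence events.

    Requires spans with negation and experiencer already resolved.
    Medication spans are grouped through the glossary here (the extraction
    schema keeps a single combined medication concept); negated spans yield
    absent-polarity events.
    """
    index = {d.doc_id: d for d in docs}
    events: list[EvidenceEvent] = []
    for span in spans:
        doc = index.get(span.doc_id)
        if doc is None:
            raise ValueError(f"span references unknown document {span.doc_id!r}")
        med_group = ""
        if span.label is ConceptLabel.MEDICATION:
            text = span.raw_text or doc.text[span.start : span.end]
            med_group = map_medication_text(text, glossary)
        variable = _concept_to_variable(span.label, span.experiencer, med_group)
        if variable is None:
            continue
        events.append(
            EvidenceEvent(
                patient_id=doc.patient_id,
                date=doc.date,
                variable=variable,
                polarity=Polarity.ABSENT if span.negated else Polarity.PRESENT,
                source=EventSource.EXTRACTED,
                provenance=f"{span.doc_id}:{span.start}-{span.end}",
            )
        )
    return events


def map_medication_text(span_text: str, glossary: MedicationGlossary) -> str:
    """Longest-token glossary lookup of a medication mention's group."""
    if not span_text.strip():
        raise ValueError("medication span text is empty")
    tokens = sorted(word_tokens(span_text), key=len, reverse=True)
    for token in tokens:
        if token in glossary:
            return glossary.lookup(token)
    return "other"


@dataclass
class PartialVariables:
    """Free-text-derived predictor values before merging with structured data."""

    patient_id: str
    values: dict = field(default_factory=dict)

    def get(self, name: str):
        return self.values.get(name, MISSING)


def carry_forward(
    events: Iterable[EvidenceEvent],
    reference_date: _dt.date,
    recency_window_days: int = 183,
) -> dict[str, PartialVariables]:
    """Resolve events into per-patient free-text predictor values.

    Historical predictors: true if any present-polarity event on/before the
    reference date (absence never overrides an earlier affirmation); false
    if only absent-polarity events; MISSING with no events.  Recency-bound
    medication predictors: true only with a present event inside the window
    (default 183 days, six months); stale or negated evidence resolves to
    false rather than MISSING, because it affirms non-recent use.  Events
    after the reference date are ignored.
    """
    by_patient: dict[str, dict[str, list[EvidenceEvent]]] = {}
    for event in events:
        if event.date > reference_date:
            continue
        by_patient.setdefault(event.patient_id, {}).setdefault(
            event.variable, []
        ).append(event)

    out: dict[str, PartialVariables] = {}
    for patient_id, per_var in by_patient.items():
        values: dict = {}
        for variable, evs in per_var.items():
            present = [e for e in evs if e.polarity is Polarity.PRESENT]
            if variable in RECENCY_PREDICTORS:
                cutoff = reference_date - _dt.timedelta(days=recency_window_days)
                values[variable] = any(e.date >= cutoff for e in present)
            elif variable == "education":
                levels = [e.value for e in present if e.value is not None]
                if levels:
                    values[variable] = max(levels, key=EDUCATION_ORDER.__getitem__)
                # level-less mentions leave education unresolved
            else:
                values[variable] = bool(present)
        out[patient_id] = PartialVariables(patient_id=patient_id, values=values)
    return out


def count_family_sentences(doc: Document) -> int:
    """Sentences mentioning a family member, the 'extensive history' signal."""
    n = 0
    for s, e in sentence_spans(doc.text):
        words = set(word_tokens(doc.text[s:e]))
        if words & set(FAMILY_TERMS):
            n += 1
    return n


def infer_family_absence(
    docs: Sequence[Document],
    partials: dict[str, PartialVariables],
    min_family_sentences: int = 3,
) -> dict[str, PartialVariables]:
    """Resolve missing parental predictors to false for well-documented families.

    A patient whose notes contain at least ``min_family_sentences``
    family-history sentences, none of which produced evidence for a parental
    predictor, is assumed not to have that risk factor (absence of mention
    in an extensive family history is informative).  Never overrides actual
    evidence; patients with thin family documentation stay MISSING.
    """
    family_counts: dict[str, int] = {}
    for doc in docs:
        family_counts[doc.patient_id] = family_counts.get(
            doc.patient_id, 0
        ) + count_family_sentences(doc)

    out: dict[str, PartialVariables] = {}
    for patient_id, partial in partials.items():
        values = dict(partial.values)
        if family_counts.get(patient_id, 0) >= min_family_sentences:
            for variable in PARENTAL_PREDICTORS:
                if variable not in values:
                    values[variable] = False
        out[patient_id] = PartialVariables(patient_id=patient_id, values=values)
    # patients with documents but no events at all still qualify
    for patient_id, n in family_counts.items():
        if patient_id not in out and n >= min_family_sentences:
            out[patient_id] = PartialVariables(
                patient_id=patient_id,
                values={v: False for v in PARENTAL_PREDICTORS},
            )
    return out


def assemble(
    record: StructuredRecord,
    partial: Optional[PartialVariables] = None,
) -> OxMISVariables:
    """Merge a structured record with free-text-derived values into the
    17-predictor vector; free-text predictors with no evidence stay MISSING."""
    if partial is not None and partial.patient_id != record.patient_id:
        raise ValueError(
            f"patient id mismatch: record {record.patient_id!r} vs "
            f"partial {partial.patient_id!r}"
        )
    partial = partial or PartialVariables(patient_id=record.patient_id)
    return OxMISVariables(
        patient_id=record.patient_id,
        age=record.age,
        sex=record.sex,
        current_episode=record.current_episode,
        first_stay_gt7days=record.first_stay_gt7days,
        previous_episodes_gt7=record.previous_episodes_gt7,
        drug_abuse=record.drug_abuse,
        alcohol_abuse=record.alcohol_abuse,
        comorbid_depression=record.comorbid_depression,
        **{name: partial.get(name) for name in FREE_TEXT_PREDICTORS},
    )


# ---------------------------------------------------------------------------
# CSV interchange

_COHORT_COLUMNS = (
    "patient_id",
    "sex",
    "age",
    "diagnosis",
    "current_episode",
    "first_stay_gt7days",
    "previous_episodes_gt7",
    "drug_abuse",
    "alcohol_abuse",
    "comorbid_depression",
)


def cohort_to_csv(records: Sequence[StructuredRecord], path: Union[str, Path]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                c: (getattr(r, c).value if isinstance(getattr(r, c), Enum) else getattr(r, c))
                for c in _COHORT_COLUMNS
            }
        )
    pd.DataFrame(rows, columns=list(_COHORT_COLUMNS)).to_csv(path, index=False)


def cohort_from_csv(path: Union[str, Path]) -> list[StructuredRecord]:
    frame = pd.read_csv(path)
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            StructuredRecord(
                patient_id=str(row.patient_id),
                sex=Sex(row.sex),
                age=float(row.age),
                diagnosis=str(row.diagnosis),
                current_episode=EpisodeType(row.current_episode),
                first_stay_gt7days=bool(row.first_stay_gt7days),
                previous_episodes_gt7=bool(row.previous_episodes_gt7),
                drug_abuse=bool(row.drug_abuse),
                alcohol_abuse=bool(row.alcohol_abuse),
                comorbid_depression=bool(row.comorbid_depression),
            )
        )
    return records


def variables_to_csv(
    variables: Sequence[OxMISVariables], path: Union[str, Path]
) -> None:
    """One row per patient, 17 predictor columns, MISSING as empty cell."""
    rows = [v.as_dict() for v in variables]
    columns = ["patient_id", *OxMISVariables.PREDICTORS]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
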