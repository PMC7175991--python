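"""Synthetic clinical corpora, cohorts, evidence and coefficients.

No real mental-health EHR can ship with this package, so every downstream
stage is exercised on synthetic data built to have the study-shaped
properties that matter:

* notes are short template sentences with concept mentions embedded at
  known character offsets (exact gold spans by construction), with
  negated mentions, parent/other attribution, and family-history
  paragraphs;
* concept frequencies follow the skew of a real annotation corpus —
  medication mentions dominate, parental suicide is rare;
* education is phrased three different ways (qualification achieved,
  institution attended, school-leaving age), the linguistic variety that
  makes that concept hard;
* a ``vocab_overlap`` dial moves mention vocabulary into a shared pool
  that also appears in unlabelled filler text, tuning extractor
  difficulty from trivially separable (0.0) to genuinely ambiguous;
* structured cohorts follow realistic marginal frequencies (60% male,
  mean age 47, 5% inpatient, ...), and per-patient evidence events
  reproduce a realistic missing-data pattern in which only education,
  benefits and two parental variables can be unknown;
* the illustrative coefficient set pins a modal patient's 12-month risk
  to the order of magnitude seen in this population (0.1–1%).

Everything is deterministic given the seed.
"""

from __future__ import annotations

import datetime as _dt
import math
import random
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .assembly import (
    EducationLevel,
    EpisodeType,
    EventSource,
    EvidenceEvent,
    Polarity,
    Sex,
    StructuredRecord,
)
from .corpus import AnnotationSpan, ConceptLabel, Corpus, DocKind, Document, Experiencer
from .scoring import CoefficientSet, logistic

# ---------------------------------------------------------------------------
# template bank

# annotated-span frequency skew of a realistic training corpus
# (relative weights; medication dominant, parental suicide rare)
_PHASE1_SKEW = {
    ConceptLabel.MEDICATION: 1774,
    ConceptLabel.SELF_HARM: 559,
    ConceptLabel.VIOLENCE: 391,
    ConceptLabel.PSYCHIATRIC_ADMISSION: 332,
    ConceptLabel.SUBSTANCE_USE_DISORDER: 190,
    ConceptLabel.BENEFITS: 188,
    ConceptLabel.EDUCATION: 174,
    ConceptLabel.SUICIDE: 19,
}

#: default expected spans per 1000 tokens, proportional to the skew above
#: and normalised to 15 total spans per 1000 tokens.
DEFAULT_CONCEPT_PROFILE: dict[ConceptLabel, float] = {
    label: 15.0 * count / sum(_PHASE1_SKEW.values())
    for label, count in _PHASE1_SKEW.items()
}


@dataclass(frozen=True)
class ConceptTemplates:
    """Surface realisations for one concept: (before, after) frames around
    a mention drawn from ``mentions``."""

    mentions: tuple[str, ...]
    affirmed: tuple[tuple[str, str], ...]
    negated: tuple[tuple[str, str], ...] = ()
    parent: tuple[tuple[str, str], ...] = ()
    other: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class TemplateBank:
    concepts: dict = field(default_factory=dict)
    shared_pool: tuple[str, ...] = ()
    filler: tuple[str, ...] = ()
    shared_filler: tuple[str, ...] = ()  # filler frames using shared-pool words
    family_filler: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for label in ConceptLabel:
            if label not in self.concepts:
                raise ValueError(f"template bank missing concept {label.value}")
            if len(self.concepts[label].affirmed) < 1:
                raise ValueError(f"concept {label.value} needs affirmed templates")


DEFAULT_TEMPLATE_BANK = TemplateBank(
    concepts={
        ConceptLabel.VIOLENCE: ConceptTemplates(
            mentions=(
                "assault",
                "affray",
                "wounding",
                "an assault conviction",
                "grievous bodily harm",
            ),
            affirmed=(
                ("Forensic record includes ", "."),
                ("He was convicted of ", " some years ago."),
                ("Police attended following ", " at the hostel."),
                ("Previous conviction for ", "."),
            ),
            negated=(
                ("No convictions for ", " on record."),
                ("He denies ", "."),
            ),
        ),
        ConceptLabel.SELF_HARM: ConceptTemplates(
            mentions=(
                "self-harm",
                "cutting",
                "an overdose",
                "self-injury",
                "cutting to the forearms",
            ),
            affirmed=(
                ("There is a documented history of ", "."),
                ("Presented to the emergency department after ", "."),
                ("She reported recent ", " during the assessment."),
                ("Longstanding pattern of ", "."),
            ),
            negated=(
                ("Denies ", " since the last review."),
                ("No episodes of ", " this year."),
            ),
        ),
        ConceptLabel.EDUCATION: ConceptTemplates(
            mentions=(
                # qualification-style
                "5 GCSEs",
                "three A-levels",
                "a BTEC diploma",
                "a nursing degree",
                # institution-style
                "the University of Cardiff",
                "the local sixth form college",
                "Oxford Brookes University",
                # leaving-age-style
                "left school at 16",
                "left school at 15",
            ),
            affirmed=(
                ("He achieved ", " before starting work."),
                ("She completed ", "."),
                ("He attended ", " from the age of 18."),
                ("She ", " without qualifications."),
            ),
        ),
        ConceptLabel.MEDICATION: ConceptTemplates(
            mentions=(
                "olanzapine",
                "risperidone",
                "quetiapine",
                "aripiprazole",
                "clozapine",
                "sertraline",
                "fluoxetine",
                "mirtazapine",
                "venlafaxine",
                "lithium",
                "olanzapine 10mg",
                "sertraline 50mg",
                "quetiapine 300mg",
            ),
            affirmed=(
                ("Continues on ", " with good effect."),
                ("Commenced on ", " this admission."),
                ("Currently prescribed ", "."),
                ("Takes ", " at night."),
            ),
            negated=(
                ("Stopped taking ", " last month."),
                ("She denies taking ", "."),
                ("Discontinued ", " due to side effects."),
            ),
        ),
        ConceptLabel.BENEFITS: ConceptTemplates(
            mentions=(
                "Universal Credit",
                "PIP",
                "ESA",
                "disability benefit",
                "housing benefit",
            ),
            affirmed=(
                ("In receipt of ", "."),
                ("He claims ", " at present."),
                ("Receives ", " and lives alone."),
            ),
            negated=(("Not in receipt of ", " currently."),),
        ),
        ConceptLabel.SUBSTANCE_USE_DISORDER: ConceptTemplates(
            mentions=(
                "alcohol dependence",
                "heavy drinking",
                "cannabis misuse",
                "opiate dependence",
                "harmful drinking",
            ),
            affirmed=(
                ("Known ", " over many years."),
                ("Long history of ", "."),
                ("Treated previously for ", "."),
            ),
            negated=(("Denies ", " at present."),),
            parent=(
                ("His father had ", " for many years."),
                ("Her mother was known for ", "."),
            ),
            other=(("Her brother has ", "."),),
        ),
        ConceptLabel.SUICIDE: ConceptTemplates(
            mentions=("suicide", "died by suicide", "took his own life"),
            affirmed=(("The notes record a serious ", " attempt in the past."),),
            parent=(
                ("His father ", " when the patient was young."),
                ("Her mother died by ", " many years ago."),
            ),
            other=(("His uncle ", " in 2005."),),
        ),
        ConceptLabel.PSYCHIATRIC_ADMISSION: ConceptTemplates(
            mentions=(
                "psychiatric admission",
                "an inpatient admission",
                "sectioned under the Mental Health Act",
                "admission to the acute ward",
            ),
            affirmed=(
                ("He required ", " in 2017."),
                ("Previous ", " lasting several weeks."),
                ("She was ", " following relapse."),
            ),
            negated=(("No previous ", "."),),
            parent=(("Her mother required ", " in the past."),),
        ),
    },
    shared_pool=("support", "history", "programme", "services", "placement"),
    filler=(
        "Seen at the community clinic today.",
        "Sleep remains poor but appetite is stable.",
        "He engaged well with the session.",
        "Plan reviewed with the wider team.",
        "Mental state settled at review.",
        "Attended the appointment on time.",
        "Care plan unchanged following discussion.",
        "Reports feeling brighter this week.",
        "Will be followed up in two weeks.",
        "Risk reviewed and unchanged today.",
    ),
    shared_filler=(
        "Good {w} at home from the housing team.",
        "Engaged with the day {w} this month.",
        "A long {w} of disturbed sleep was described.",
        "Referred to local {w} for ongoing input.",
        "The {w} was reviewed at the meeting.",
    ),
    family_filler=(
        "His mother works as a teacher.",
        "Her father lives locally and visits often.",
        "She has two siblings in the area.",
        "His parents separated when he was young.",
        "Her grandmother helped to raise her.",
        "His brother keeps in regular contact.",
    ),
)

# parent/other attribution per concept: only the concepts whose parent
# templates exist can be attributed, suicide mentions mostly are.
DEFAULT_PARENT_RATE: dict[ConceptLabel, float] = {
    ConceptLabel.SUICIDE: 0.6,
    ConceptLabel.SUBSTANCE_USE_DISORDER: 0.15,
    ConceptLabel.PSYCHIATRIC_ADMISSION: 0.10,
}

DEFAULT_OTHER_RATE: dict[ConceptLabel, float] = {
    ConceptLabel.SUICIDE: 0.1,
    ConceptLabel.SUBSTANCE_USE_DISORDER: 0.05,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the corpus generator; defaults are the study conditions:
    shared-vocabulary fraction 0.2 and a corpus of roughly 2,000 gold spans
    (about 1,300 documents for 225 patients)."""

    n_patients: int = 225
    docs_per_patient_mean: float = 6.0
    concept_frequency_profile: dict = field(
        default_factory=lambda: dict(DEFAULT_CONCEPT_PROFILE)
    )
    negation_rate: float = 0.10
    parent_attribution_rate: dict = field(
        default_factory=lambda: dict(DEFAULT_PARENT_RATE)
    )
    other_attribution_rate: dict = field(
        default_factory=lambda: dict(DEFAULT_OTHER_RATE)
    )
    vocab_overlap: float = 0.2
    family_history_rate: float = 0.30
    sentences_per_doc: tuple[int, int] = (6, 16)
    tokens_per_sentence: float = 9.0  # calibration constant for the profile
    end_date: _dt.date = _dt.date(2019, 12, 31)
    window_days: int = 5 * 365  # dates span 5 years to exercise carry-forward
    seed: int = 0
    templates: TemplateBank = DEFAULT_TEMPLATE_BANK

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        rates = [
            self.negation_rate,
            self.vocab_overlap,
            self.family_history_rate,
            *self.parent_attribution_rate.values(),
            *self.other_attribution_rate.values(),
        ]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(f < 0 for f in self.concept_frequency_profile.values()):
            raise ValueError("concept frequencies must be non-negative")


def _sample_concept(
    rng: random.Random, per_sentence: dict[ConceptLabel, float]
) -> Optional[ConceptLabel]:
    r = rng.random()
    acc = 0.0
    for label, p in per_sentence.items():
        acc += p
        if r < acc:
            return label
    return None


def _build_concept_sentence(
    rng: random.Random, config: GeneratorConfig, label: ConceptLabel
) -> tuple[str, int, int, bool, Experiencer]:
    """Return (sentence, mention_start, mention_end, negated, experiencer)."""
    templates = config.templates.concepts[label]
    negated = False
    experiencer = Experiencer.PATIENT
    frames = templates.affirmed
    if templates.parent and rng.random() < config.parent_attribution_rate.get(
        label, 0.0
    ):
        frames = templates.parent
        experiencer = Experiencer.PARENT
    elif templates.other and rng.random() < config.other_attribution_rate.get(
        label, 0.0
    ):
        frames = templates.other
        experiencer = Experiencer.OTHER
    elif templates.negated and rng.random() < config.negation_rate:
        frames = templates.negated
        negated = True
    before, after = rng.choice(frames)
    if (
        label is not ConceptLabel.EDUCATION
        and config.templates.shared_pool
        and rng.random() < config.vocab_overlap
    ):
        mention = rng.choice(config.templates.shared_pool)
    else:
        mention = rng.choice(templates.mentions)
    sentence = before + mention + after
    return sentence, len(before), len(before) + len(mention), negated, experiencer


def _filler_sentence(rng: random.Random, config: GeneratorConfig) -> str:
    bank = config.templates
    if bank.shared_pool and bank.shared_filler and rng.random() < config.vocab_overlap:
        frame = rng.choice(bank.shared_filler)
        return frame.format(w=rng.choice(bank.shared_pool))
    return rng.choice(bank.filler)


def generate_corpus(config: GeneratorConfig = GeneratorConfig()) -> Corpus:
    """Generate a corpus with exact gold spans; deterministic given seed."""
    config.validate()
    rng = random.Random(config.seed)
    per_sentence = {
        label: freq * config.tokens_per_sentence / 1000.0
        for label, freq in config.concept_frequency_profile.items()
    }
    documents: list[Document] = []
    gold: list[AnnotationSpan] = []
    for p in range(config.n_patients):
        patient_id = f"P{p + 1:04d}"
        n_docs = max(1, int(rng.gauss(config.docs_per_patient_mean, 2.0) + 0.5))
        offsets = sorted(rng.randrange(config.window_days) for _ in range(n_docs))
        for d, day_offset in enumerate(offsets):
            doc_id = f"{patient_id}-D{d + 1:03d}"
            date = config.end_date - _dt.timedelta(
                days=config.window_days - day_offset
            )
            kind = DocKind.NOTE if rng.random() < 0.8 else DocKind.CORRESPONDENCE
            parts: list[str] = []
            cursor = 0
            spans: list[AnnotationSpan] = []
            n_sentences = rng.randint(*config.sentences_per_doc)
            sentence_plan: list[Optional[ConceptLabel]] = [
                _sample_concept(rng, per_sentence) for _ in range(n_sentences)
            ]
            family_sentences: list[str] = []
            if rng.random() < config.family_history_rate:
                family_sentences = [
                    rng.choice(config.templates.family_filler)
                    for _ in range(rng.randint(3, 5))
                ]
            for label in sentence_plan:
                if label is None:
                    sentence = _filler_sentence(rng, config)
                else:
                    sentence, m_start, m_end, negated, exp = _build_concept_sentence(
                        rng, config, label
                    )
                    spans.append(
                        AnnotationSpan(
                            doc_id=doc_id,
                            start=cursor + m_start,
                            end=cursor + m_end,
                            label=label,
                            negated=negated,
                            experiencer=exp,
                            raw_text=sentence[m_start:m_end],
                        )
                    )
                parts.append(sentence)
                cursor += len(sentence) + 1  # sentences joined by one space
            for sentence in family_sentences:
                parts.append(sentence)
                cursor += len(sentence) + 1
            text = " ".join(parts)
            documents.append(
                Document(
                    doc_id=doc_id,
                    patient_id=patient_id,
                    date=date,
                    kind=kind,
                    text=text,
                )
            )
            # drop accidental duplicate (start, end, label) triples
            seen = set()
            for span in spans:
                if span.identity not in seen:
                    seen.add(span.identity)
                    gold.append(span)
    corpus = Corpus(documents=documents, gold=gold)
    corpus.validate()
    return corpus


def easy_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Disjoint-vocabulary conditions: no shared pool, no lexical ambiguity."""
    return replace(
        GeneratorConfig(seed=seed), vocab_overlap=0.0, **overrides
    )


# ---------------------------------------------------------------------------
# structured cohort


@dataclass(frozen=True)
class CohortRates:
    """Marginal frequencies for structured fields (realistic defaults)."""

    male: float = 0.60
    age_mean: float = 47.0
    age_sd: float = 10.8
    age_bounds: tuple[float, float] = (15.0, 65.0)
    inpatient: float = 0.05
    first_stay_gt7days: float = 0.88
    previous_episodes_gt7: float = 0.61
    drug_abuse: float = 0.32
    alcohol_abuse: float = 0.32
    comorbid_depression: float = 0.02


_DIAGNOSES = ("F20", "F22", "F25", "F29", "F31", "F30")
_DIAGNOSIS_WEIGHTS = (0.45, 0.05, 0.15, 0.05, 0.25, 0.05)


def generate_cohort(
    n: int, seed: int = 0, rates: CohortRates = CohortRates()
) -> list[StructuredRecord]:
    """Structured records for ``n`` patients; deterministic given seed."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = random.Random(seed)
    lo, hi = rates.age_bounds
    records = []
    for p in range(n):
        age = min(max(rng.gauss(rates.age_mean, rates.age_sd), lo), hi)
        records.append(
            StructuredRecord(
                patient_id=f"P{p + 1:04d}",
                sex=Sex.MALE if rng.random() < rates.male else Sex.FEMALE,
                age=round(age, 1),
                diagnosis=rng.choices(_DIAGNOSES, weights=_DIAGNOSIS_WEIGHTS)[0],
                current_episode=(
                    EpisodeType.INPATIENT
                    if rng.random() < rates.inpatient
                    else EpisodeType.OUTPATIENT
                ),
                first_stay_gt7days=rng.random() < rates.first_stay_gt7days,
                previous_episodes_gt7=rng.random() < rates.previous_episodes_gt7,
                drug_abuse=rng.random() < rates.drug_abuse,
                alcohol_abuse=rng.random() < rates.alcohol_abuse,
                comorbid_depression=rng.random() < rates.comorbid_depression,
            )
        )
    return records


# ---------------------------------------------------------------------------
# evidence events with a realistic missing-data pattern


@dataclass(frozen=True)
class EvidenceProfile:
    """Presence and missingness rates for the free-text predictors.

    ``missing_*`` is the probability that the notes contain no usable
    evidence at all; only four predictors can be missing, matching the
    observed pattern that the rest are always documented somewhere.
    Presence rates are conditional on evidence existing.
    """

    violent_crime: float = 0.28
    self_harm: float = 0.46
    antipsychotic_recent: float = 0.89
    antidepressant_recent: float = 0.33
    benefits: float = 0.72
    parental_psych_admission: float = 0.08
    parental_substance_disorder: float = 0.04
    parental_suicide: float = 0.02
    education_levels: tuple[float, float, float] = (0.62, 0.24, 0.14)
    missing_education: float = 0.26
    missing_benefits: float = 0.25
    missing_parental_psych_admission: float = 0.16
    missing_parental_substance_disorder: float = 0.07


def generate_cohort_events(
    records: Sequence[StructuredRecord],
    reference_date: _dt.date,
    seed: int = 0,
    profile: EvidenceProfile = EvidenceProfile(),
    recency_window_days: int = 183,
) -> list[EvidenceEvent]:
    """Per-patient evidence events as a manual chart review would record them.

    Definitive negatives become absent-polarity events (a reviewer records
    "no history of X"); predictors with a missingness rate are omitted
    entirely with that probability and stay MISSING downstream.  Recent
    medication use gets an event inside the recency window; non-recent use
    a stale or absent one.
    """
    rng = random.Random(seed)
    events: list[EvidenceEvent] = []

    def add(patient_id, variable, polarity, days_back, value=None):
        events.append(
            EvidenceEvent(
                patient_id=patient_id,
                date=reference_date - _dt.timedelta(days=days_back),
                variable=variable,
                polarity=polarity,
                source=EventSource.EXTRACTED,
                value=value,
            )
        )

    for record in records:
        pid = record.patient_id
        for variable, present_rate, missing_rate in (
            ("violent_crime", profile.violent_crime, 0.0),
            ("self_harm", profile.self_harm, 0.0),
            ("benefits", profile.benefits, profile.missing_benefits),
            (
                "parental_psych_admission",
                profile.parental_psych_admission,
                profile.missing_parental_psych_admission,
            ),
            (
                "parental_substance_disorder",
                profile.parental_substance_disorder,
                profile.missing_parental_substance_disorder,
            ),
            ("parental_suicide", profile.parental_suicide, 0.0),
        ):
            if rng.random() < missing_rate:
                continue
            present = rng.random() < present_rate
            add(
                pid,
                variable,
                Polarity.PRESENT if present else Polarity.ABSENT,
                days_back=rng.randint(1, 4 * 365),
            )
        for variable, recent_rate in (
            ("antipsychotic_recent", profile.antipsychotic_recent),
            ("antidepressant_recent", profile.antidepressant_recent),
        ):
            if rng.random() < recent_rate:
                add(pid, variable, Polarity.PRESENT, rng.randint(1, recency_window_days - 1))
            elif rng.random() < 0.5:  # documented non-recent use
                add(pid, variable, Polarity.PRESENT, rng.randint(recency_window_days + 1, 4 * 365))
            else:  # documented never-use
                add(pid, variable, Polarity.ABSENT, rng.randint(1, 4 * 365))
        if rng.random() >= profile.missing_education:
            level = rng.choices(
                list(EducationLevel), weights=profile.education_levels
            )[0]
            add(
                pid,
                "education",
                Polarity.PRESENT,
                rng.randint(1, 4 * 365),
                value=level,
            )
    return events


# ---------------------------------------------------------------------------
# illustrative coefficients

# plausible log-odds magnitudes per predictor (jittered by seed); signs
# follow the epidemiology: prior self-harm and parental suicide strongest.
_BASE_WEIGHTS: dict[str, dict[str, float]] = {
    "sex": {"male": 0.40},
    "current_episode": {"inpatient": 0.80},
    "first_stay_gt7days": {"true": 0.20},
    "previous_episodes_gt7": {"true": 0.30},
    "drug_abuse": {"true": 0.45},
    "alcohol_abuse": {"true": 0.30},
    "comorbid_depression": {"true": 0.40},
    "violent_crime": {"true": 0.35},
    "self_harm": {"true": 0.90},
    "antipsychotic_recent": {"true": 0.25},
    "antidepressant_recent": {"true": 0.35},
    "benefits": {"true": 0.20},
    "education": {"upper_secondary": -0.10, "post_secondary": -0.30},
    "parental_psych_admission": {"true": 0.30},
    "parental_substance_disorder": {"true": 0.30},
    "parental_suicide": {"true": 0.70},
}

#: the modal patient used to anchor the intercept: a 47-year-old male
#: outpatient on recent antipsychotics, long first stay, many previous
#: episodes, on benefits, no other risk factors.
_MODAL_CATEGORIES: dict[str, str] = {
    "sex": "male",
    "current_episode": "outpatient",
    "first_stay_gt7days": "true",
    "previous_episodes_gt7": "true",
    "drug_abuse": "false",
    "alcohol_abuse": "false",
    "comorbid_depression": "false",
    "violent_crime": "false",
    "self_harm": "false",
    "antipsychotic_recent": "true",
    "antidepressant_recent": "false",
    "benefits": "true",
    "education": "secondary",
    "parental_psych_admission": "false",
    "parental_substance_disorder": "false",
    "parental_suicide": "false",
}


def generate_coefficients(seed: int = 0) -> CoefficientSet:
    """An illustrative coefficient set (not published weights).

    Weights are jittered around plausible magnitudes; the intercept is
    solved so the modal patient's 12-month risk is 0.4% regardless of
    seed, keeping cohort risks on the 0.1–1% order of magnitude.
    """
    rng = random.Random(seed)
    predictors = {
        predictor: {
            category: round(base * rng.uniform(0.8, 1.2), 4)
            for category, base in categories.items()
        }
        for predictor, categories in _BASE_WEIGHTS.items()
    }
    age_weight = round(-0.012 * rng.uniform(0.8, 1.2), 5)
    age_reference = 47.0
    modal_sum = sum(
        predictors[p].get(c, 0.0) for p, c in _MODAL_CATEGORIES.items()
    )
    target = 0.004  # modal 12-month risk anchor
    intercept = math.log(target / (1 - target)) - modal_sum
    coeffs = CoefficientSet(
        name="synthetic-illustrative",
        version=1,
        intercept=round(intercept, 4),
        age_weight=age_weight,
        age_reference=age_reference,
        predictors=predictors,
    )
    # by construction the modal patient sits inside the anchor band
    assert 0.001 < logistic(coeffs.intercept + modal_sum) < 0.01
    return coeffs
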