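"""Evidence mapping, carry-forward, family-absence inference, assembly."""

import datetime as dt

import pytest

from oxmisnlp.assembly import (
    MISSING,
    EducationLevel,
    EpisodeType,
    EventSource,
    EvidenceEvent,
    Polarity,
    Sex,
    StructuredRecord,
    assemble,
    carry_forward,
    cohort_from_csv,
    cohort_to_csv,
    infer_family_absence,
    spans_to_events,
)
from oxmisnlp.corpus import ConceptLabel, Experiencer
from oxmisnlp.synthetic import generate_cohort, generate_cohort_events

from conftest import make_doc, make_span

REF = dt.date(2019, 12, 31)


def event(variable, days_back, polarity=Polarity.PRESENT, patient="p1", value=None):
    return EvidenceEvent(
        patient_id=patient,
        date=REF - dt.timedelta(days=days_back),
        variable=variable,
        polarity=polarity,
        source=EventSource.EXTRACTED,
        value=value,
    )


def record(patient="p1", **kw):
    defaults = dict(
        patient_id=patient,
        sex=Sex.MALE,
        age=47.0,
        diagnosis="F20",
        current_episode=EpisodeType.OUTPATIENT,
        first_stay_gt7days=True,
        previous_episodes_gt7=True,
        drug_abuse=False,
        alcohol_abuse=False,
        comorbid_depression=False,
    )
    defaults.update(kw)
    return StructuredRecord(**defaults)


# --- spans_to_events -------------------------------------------------------


def test_affirmed_self_harm_span_yields_present_event():
    doc = make_doc("Documented history of self-harm.")
    span = make_span(doc, "self-harm", ConceptLabel.SELF_HARM)
    (ev,) = spans_to_events([span], [doc])
    assert (ev.variable, ev.polarity) == ("self_harm", Polarity.PRESENT)
    assert ev.patient_id == "p1" and ev.date == doc.date


def test_negated_antipsychotic_yields_absent_event():
    doc = make_doc("XX stopped taking olanzapine.")
    span = make_span(doc, "olanzapine", ConceptLabel.MEDICATION, negated=True)
    (ev,) = spans_to_events([span], [doc])
    assert (ev.variable, ev.polarity) == ("antipsychotic_recent", Polarity.ABSENT)


def test_antidepressant_group_routes_to_antidepressant_variable():
    doc = make_doc("Commenced on sertraline 50mg.")
    span = make_span(doc, "sertraline 50mg", ConceptLabel.MEDICATION)
    (ev,) = spans_to_events([span], [doc])
    assert ev.variable == "antidepressant_recent"


def test_other_group_medication_yields_no_event():
    doc = make_doc("Takes lithium at night.")
    span = make_span(doc, "lithium", ConceptLabel.MEDICATION)
    assert spans_to_events([span], [doc]) == []


def test_parent_suicide_maps_to_parental_variable():
    doc = make_doc("His father died by suicide.")
    span = make_span(
        doc, "suicide", ConceptLabel.SUICIDE, experiencer=Experiencer.PARENT
    )
    (ev,) = spans_to_events([span], [doc])
    assert ev.variable == "parental_suicide"


def test_non_parent_suicide_span_yields_no_event():
    doc = make_doc("His uncle died by suicide.")
    span = make_span(
        doc, "suicide", ConceptLabel.SUICIDE, experiencer=Experiencer.OTHER
    )
    assert spans_to_events([span], [doc]) == []


def test_unknown_document_rejected():
    doc = make_doc("history of self-harm")
    span = make_span(doc, "self-harm", ConceptLabel.SELF_HARM)
    with pytest.raises(ValueError, match="unknown document"):
        spans_to_events([span], [])


# --- carry_forward ---------------------------------------------------------


def test_historical_variable_carries_forward_years():
    partial = carry_forward([event("self_harm", 4 * 365)], REF)["p1"]
    assert partial.get("self_harm") is True


def test_stale_medication_resolves_false_not_missing():
    partial = carry_forward([event("antipsychotic_recent", 300)], REF)["p1"]
    assert partial.get("antipsychotic_recent") is False


def test_recent_medication_within_window_true():
    partial = carry_forward([event("antipsychotic_recent", 100)], REF)["p1"]
    assert partial.get("antipsychotic_recent") is True


def test_no_events_leaves_variable_missing():
    partial = carry_forward([event("self_harm", 10)], REF)["p1"]
    assert partial.get("benefits") is MISSING


def test_absence_never_overrides_presence_for_historical():
    events = [
        event("violent_crime", 900, Polarity.PRESENT),
        event("violent_crime", 10, Polarity.ABSENT),
    ]
    assert carry_forward(events, REF)["p1"].get("violent_crime") is True


def test_events_after_reference_date_excluded():
    future = EvidenceEvent(
        patient_id="p1",
        date=REF + dt.timedelta(days=30),
        variable="self_harm",
        polarity=Polarity.PRESENT,
        source=EventSource.EXTRACTED,
    )
    assert carry_forward([future], REF) == {}


def test_education_highest_level_wins():
    events = [
        event("education", 200, value=EducationLevel.SECONDARY),
        event("education", 900, value=EducationLevel.POST_SECONDARY),
    ]
    assert carry_forward(events, REF)["p1"].get("education") is EducationLevel.POST_SECONDARY


def test_education_without_level_stays_unresolved():
    partial = carry_forward([event("education", 100)], REF)["p1"]
    assert partial.get("education") is MISSING


# --- infer_family_absence --------------------------------------------------

FAMILY_TEXT = (
    "His mother works locally. His father visits weekly. "
    "Her parents separated early. His brother keeps contact. "
    "His grandmother helped raise him."
)


def test_extensive_family_history_resolves_parental_absent():
    doc = make_doc(FAMILY_TEXT)
    partials = carry_forward([event("self_harm", 10)], REF)
    updated = infer_family_absence([doc], partials, min_family_sentences=3)
    p = updated["p1"]
    assert p.get("parental_suicide") is False
    assert p.get("parental_substance_disorder") is False
    assert p.get("parental_psych_admission") is False


def test_no_family_sentences_stays_missing():
    doc = make_doc("Routine review. Medication unchanged.")
    partials = carry_forward([event("self_harm", 10)], REF)
    updated = infer_family_absence([doc], partials, min_family_sentences=3)
    assert updated["p1"].get("parental_suicide") is MISSING


def test_inference_never_overrides_evidence():
    doc = make_doc(FAMILY_TEXT)
    partials = carry_forward([event("parental_suicide", 100)], REF)
    updated = infer_family_absence([doc], partials, min_family_sentences=3)
    assert updated["p1"].get("parental_suicide") is True


# --- assemble --------------------------------------------------------------


def test_assemble_structured_only_leaves_free_text_missing():
    v = assemble(record(current_episode=EpisodeType.INPATIENT))
    assert v.current_episode is EpisodeType.INPATIENT
    assert len(v.missing_predictors()) == 9


def test_assemble_patient_mismatch_rejected():
    partials = carry_forward([event("self_harm", 10, patient="p2")], REF)
    with pytest.raises(ValueError, match="mismatch"):
        assemble(record(patient="p1"), partials["p2"])


def test_assemble_idempotent_and_complete():
    events = [
        event("self_harm", 10),
        event("violent_crime", 10, Polarity.ABSENT),
        event("benefits", 10),
        event("antipsychotic_recent", 10),
        event("antidepressant_recent", 10, Polarity.ABSENT),
        event("education", 10, value=EducationLevel.SECONDARY),
        event("parental_suicide", 10, Polarity.ABSENT),
        event("parental_substance_disorder", 10, Polarity.ABSENT),
        event("parental_psych_admission", 10, Polarity.ABSENT),
    ]
    partial = carry_forward(events, REF)["p1"]
    v1 = assemble(record(), partial)
    v2 = assemble(record(), partial)
    assert v1 == v2
    assert v1.missing_predictors() == []


def test_monotonicity_adding_present_event():
    base = [event("violent_crime", 500, Polarity.ABSENT)]
    with_present = base + [event("violent_crime", 600, Polarity.PRESENT)]
    v_base = carry_forward(base, REF)["p1"].get("violent_crime")
    v_more = carry_forward(with_present, REF)["p1"].get("violent_crime")
    assert v_base is False and v_more is True


def test_cohort_missingness_profile():
    """Only four predictors can be missing, at their configured rates."""
    n = 400
    cohort = generate_cohort(n, seed=21)
    events = generate_cohort_events(cohort, REF, seed=22)
    partials = carry_forward(events, REF)
    missing_counts: dict[str, int] = {}
    for rec in cohort:
        v = assemble(rec, partials.get(rec.patient_id))
        for name in v.missing_predictors():
            missing_counts[name] = missing_counts.get(name, 0) + 1
    assert set(missing_counts) <= {
        "education",
        "benefits",
        "parental_psych_admission",
        "parental_substance_disorder",
    }
    assert abs(missing_counts["education"] / n - 0.26) < 0.07
    assert abs(missing_counts["benefits"] / n - 0.25) < 0.07
    assert abs(missing_counts["parental_psych_admission"] / n - 0.16) < 0.07
    assert abs(missing_counts["parental_substance_disorder"] / n - 0.07) < 0.05


def test_cohort_csv_roundtrip(tmp_path):
    cohort = generate_cohort(12, seed=3)
    path = tmp_path / "cohort.csv"
    cohort_to_csv(cohort, path)
    assert cohort_from_csv(path) == cohort
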