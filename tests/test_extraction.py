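"""Concept extraction: tagging, negation, experiencer, medication mapping."""

import pytest

from oxmisnlp.corpus import AnnotationSpan, ConceptLabel, Corpus, Experiencer
from oxmisnlp.extraction import (
    attribute_experiencer,
    bio_to_spans,
    detect_negation,
    fine_tune,
    predict,
    predict_corpus,
    spans_to_bio,
    train,
)
from oxmisnlp.lexicons import NegationLexicon
from oxmisnlp.assembly import map_medication_text
from oxmisnlp.lexicons import DEFAULT_MEDICATION_GLOSSARY
from oxmisnlp.evaluation import match_spans, micro_average
from oxmisnlp.text import tokenize

from conftest import make_doc, make_span


# --- negation --------------------------------------------------------------


def test_stopped_taking_negates_medication_mention():
    doc = make_doc("XX stopped taking olanzapine.")
    span = make_span(doc, "olanzapine", ConceptLabel.MEDICATION)
    assert detect_negation(doc, span) is True


def test_same_sentence_without_trigger_is_affirmed():
    doc = make_doc("XX is taking olanzapine.")
    span = make_span(doc, "olanzapine", ConceptLabel.MEDICATION)
    assert detect_negation(doc, span) is False


@pytest.mark.parametrize("gap", [1, 2, 3, 4, 5, 6, 7])
def test_pre_trigger_window_boundary(gap):
    """A trigger k token-steps before the span negates iff k <= window."""
    lexicon = NegationLexicon(
        pre_triggers=("no",), post_triggers=(), pseudo_triggers=(), scope_window=5
    )
    fillers = " ".join(f"w{i}" for i in range(gap - 1))
    text = ("no " + (fillers + " " if fillers else "") + "overdose.").strip()
    doc = make_doc(text)
    span = make_span(doc, "overdose", ConceptLabel.SELF_HARM)
    assert detect_negation(doc, span, lexicon) is (gap <= 5)


def test_pseudo_trigger_cancels_negation():
    lexicon = NegationLexicon(
        pre_triggers=("no",),
        post_triggers=(),
        pseudo_triggers=("no increase in",),
        scope_window=5,
    )
    doc = make_doc("There was no increase in self-harm.")
    span = make_span(doc, "self-harm", ConceptLabel.SELF_HARM)
    assert detect_negation(doc, span, lexicon) is False


def test_negation_does_not_cross_sentence_boundary():
    doc = make_doc("He denies violence. He reported an overdose.")
    span = make_span(doc, "overdose", ConceptLabel.SELF_HARM)
    assert detect_negation(doc, span) is False


def test_post_trigger_negates():
    lexicon = NegationLexicon(
        pre_triggers=(), post_triggers=("was ruled out",),
        pseudo_triggers=(), scope_window=5,
    )
    doc = make_doc("An overdose was ruled out.")
    span = make_span(doc, "overdose", ConceptLabel.SELF_HARM)
    assert detect_negation(doc, span, lexicon) is True


def test_trigger_lists_must_be_disjoint():
    with pytest.raises(ValueError):
        NegationLexicon(
            pre_triggers=("no",), post_triggers=("no",), pseudo_triggers=()
        )


# --- experiencer -----------------------------------------------------------


def test_father_before_span_attributes_parent():
    doc = make_doc("His father died by suicide.")
    span = make_span(doc, "suicide", ConceptLabel.SUICIDE)
    assert attribute_experiencer(doc, span) is Experiencer.PARENT


def test_default_experiencer_is_patient():
    doc = make_doc("XX has a history of self-harm.")
    span = make_span(doc, "self-harm", ConceptLabel.SELF_HARM)
    assert attribute_experiencer(doc, span) is Experiencer.PATIENT


def test_brother_attributes_other():
    doc = make_doc("Her brother misuses alcohol dependence.")
    span = make_span(doc, "alcohol dependence", ConceptLabel.SUBSTANCE_USE_DISORDER)
    assert attribute_experiencer(doc, span) is Experiencer.OTHER


def test_family_term_in_previous_sentence_does_not_leak():
    doc = make_doc("His father visited. A history of self-harm was noted.")
    span = make_span(doc, "self-harm", ConceptLabel.SELF_HARM)
    assert attribute_experiencer(doc, span) is Experiencer.PATIENT


# --- medication glossary ---------------------------------------------------


@pytest.mark.parametrize(
    "text,group",
    [
        ("Olanzapine", "antipsychotic"),
        ("vitamin D", "other"),
        ("sertraline 50mg", "antidepressant"),
        ("lithium", "other"),
    ],
)
def test_map_medication(text, group):
    assert map_medication_text(text, DEFAULT_MEDICATION_GLOSSARY) == group


def test_map_medication_rejects_empty():
    with pytest.raises(ValueError):
        map_medication_text("  ", DEFAULT_MEDICATION_GLOSSARY)


# --- BIO encode/decode -----------------------------------------------------


def test_bio_roundtrip_on_generated_doc(tiny_corpus):
    for doc in tiny_corpus.documents:
        gold = sorted(tiny_corpus.spans_for(doc.doc_id), key=lambda s: s.start)
        if not gold:
            continue
        tokens = tokenize(doc.text)
        tags = spans_to_bio(tokens, gold)
        decoded = bio_to_spans(doc, tokens, tags)
        assert [(s.start, s.end, s.label) for s in decoded] == [
            (s.start, s.end, s.label) for s in gold
        ]


# --- training and prediction ----------------------------------------------


def test_training_is_deterministic(small_easy_split):
    train_corpus, test_corpus = small_easy_split
    doc = test_corpus.documents[0]
    m1 = train(train_corpus, seed=3)
    m2 = train(train_corpus, seed=3)
    assert predict(m1, doc) == predict(m2, doc)


def test_empty_corpus_training_rejected():
    with pytest.raises(ValueError):
        train(Corpus([], []))


def test_closed_label_set_single_label_corpus():
    docs, spans = [], []
    for i in range(30):
        doc = make_doc(f"Currently prescribed olanzapine today.", doc_id=f"m{i}")
        docs.append(doc)
        spans.append(make_span(doc, "olanzapine", ConceptLabel.MEDICATION))
    model = train(Corpus(docs, spans), seed=0)
    probe = make_doc("Currently prescribed olanzapine and reported an overdose.")
    labels = {s.label for s in predict(model, probe)}
    assert labels <= {ConceptLabel.MEDICATION}


def test_predict_empty_text_returns_no_spans(small_easy_model):
    doc = make_doc(" ")
    assert predict(small_easy_model, doc) == []


def test_held_out_f1_on_easy_corpus(small_easy_split, small_easy_model):
    _, test_corpus = small_easy_split
    pred = predict_corpus(small_easy_model, test_corpus)
    micro = micro_average(list(match_spans(test_corpus.gold, pred).values()))
    assert micro.f1 >= 0.95


def test_predicted_spans_satisfy_offset_invariants(small_easy_split, small_easy_model):
    _, test_corpus = small_easy_split
    for doc in test_corpus.documents:
        for s in predict(small_easy_model, doc):
            assert 0 <= s.start < s.end <= len(doc.text)
            assert s.raw_text == doc.text[s.start : s.end]


# --- fine-tuning -----------------------------------------------------------


def test_fine_tune_empty_judgments_keeps_predictions(small_easy_split, small_easy_model):
    _, test_corpus = small_easy_split
    refined = fine_tune(small_easy_model, [], test_corpus.documents, seed=0)
    assert refined.phase == 2
    doc = test_corpus.documents[0]
    assert predict(refined, doc) == predict(small_easy_model, doc)


def test_fine_tune_unknown_document_rejected(small_easy_model):
    ghost = AnnotationSpan(
        doc_id="nope", start=0, end=3, label=ConceptLabel.MEDICATION
    )
    with pytest.raises(Exception, match="unknown document"):
        fine_tune(small_easy_model, [(ghost, True)], [], seed=0)


def test_fine_tune_all_accept_is_stable(small_easy_split, small_easy_model):
    train_corpus, test_corpus = small_easy_split
    before = micro_average(
        list(
            match_spans(
                test_corpus.gold, predict_corpus(small_easy_model, test_corpus)
            ).values()
        )
    ).f1
    # accept the model's own correct output on training documents
    judgments = []
    for doc in train_corpus.documents[:40]:
        gold_keys = {
            (s.start, s.end, s.label) for s in train_corpus.spans_for(doc.doc_id)
        }
        for s in predict(small_easy_model, doc):
            if (s.start, s.end, s.label) in gold_keys:
                judgments.append((s, True))
    refined = fine_tune(small_easy_model, judgments, train_corpus.documents, seed=0)
    after = micro_average(
        list(
            match_spans(
                test_corpus.gold, predict_corpus(refined, test_corpus)
            ).values()
        )
    ).f1
    assert after >= before - 0.05


def test_fine_tune_rejection_suppresses_a_label(small_easy_split, small_easy_model):
    train_corpus, test_corpus = small_easy_split
    target = ConceptLabel.BENEFITS
    judgments = []
    for doc in train_corpus.documents:
        for s in predict(small_easy_model, doc):
            if s.label is target:
                judgments.append((s, False))
    assert judgments, "model should predict some benefits spans to reject"
    refined = fine_tune(small_easy_model, judgments, train_corpus.documents, seed=0)
    n_before = sum(
        1 for s in predict_corpus(small_easy_model, test_corpus) if s.label is target
    )
    n_after = sum(
        1 for s in predict_corpus(refined, test_corpus) if s.label is target
    )
    assert n_after < n_before
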