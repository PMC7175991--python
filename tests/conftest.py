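import datetime as dt

import pytest

from oxmisnlp.corpus import (
    AnnotationSpan,
    ConceptLabel,
    Corpus,
    DocKind,
    Document,
)
from oxmisnlp.extraction import train
from oxmisnlp.pipeline import split_corpus
from oxmisnlp.synthetic import GeneratorConfig, easy_config, generate_corpus


def make_doc(text: str, doc_id: str = "d1", patient_id: str = "p1") -> Document:
    return Document(
        doc_id=doc_id,
        patient_id=patient_id,
        date=dt.date(2019, 6, 1),
        kind=DocKind.NOTE,
        text=text,
    )


def make_span(doc: Document, needle: str, label: ConceptLabel, **kwargs):
    start = doc.text.index(needle)
    return AnnotationSpan(
        doc_id=doc.doc_id,
        start=start,
        end=start + len(needle),
        label=label,
        raw_text=needle,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_easy_corpus() -> Corpus:
    """A small disjoint-vocabulary corpus (fast to train on)."""
    return generate_corpus(easy_config(seed=11, n_patients=40))


@pytest.fixture(scope="session")
def small_easy_split(small_easy_corpus):
    return split_corpus(small_easy_corpus, 0.8)


@pytest.fixture(scope="session")
def small_easy_model(small_easy_split):
    train_corpus, _ = small_easy_split
    return train(train_corpus, seed=3)


@pytest.fixture(scope="session")
def tiny_corpus() -> Corpus:
    """A ten-patient corpus for structural tests."""
    return generate_corpus(GeneratorConfig(seed=5, n_patients=10))
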