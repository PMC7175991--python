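"""Rule-based span attributes: negation and experiencer.

Shows the trigger-window negation test ("stopped taking olanzapine") and
family-term experiencer attribution ("His father died by suicide").
"""

import datetime as dt

from oxmisnlp import (
    AnnotationSpan,
    ConceptLabel,
    DocKind,
    Document,
    attribute_experiencer,
    detect_negation,
)


def doc_with_span(text: str, needle: str, label: ConceptLabel):
    d = Document("d1", "p1", dt.date(2019, 1, 1), DocKind.NOTE, text)
    i = text.index(needle)
    return d, AnnotationSpan("d1", i, i + len(needle), label, raw_text=needle)


for text in ("XX stopped taking olanzapine.", "XX is taking olanzapine."):
    d, s = doc_with_span(text, "olanzapine", ConceptLabel.MEDICATION)
    print(f"{text!r:42s} negated={detect_negation(d, s)}")

for text, needle, label in (
    ("His father died by suicide.", "suicide", ConceptLabel.SUICIDE),
    ("XX has a history of self-harm.", "self-harm", ConceptLabel.SELF_HARM),
    ("Her brother misuses alcohol.", "alcohol", ConceptLabel.SUBSTANCE_USE_DISORDER),
):
    d, s = doc_with_span(text, needle, label)
    print(f"{text!r:42s} experiencer={attribute_experiencer(d, s).value}")
# A negated mention becomes absent-polarity evidence; only parent-attributed
# mentions feed the three parental predictors.
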