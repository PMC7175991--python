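"""Generate a synthetic annotated corpus and inspect its shape.

Builds a small clinical-note corpus with gold concept spans, prints the
per-concept span tally (medication should dominate, parental suicide be
rare) and one annotated sentence.
"""

from oxmisnlp import ConceptLabel, generate_corpus
from oxmisnlp.corpus import concept_span_counts
from oxmisnlp.synthetic import GeneratorConfig

corpus = generate_corpus(GeneratorConfig(seed=7, n_patients=40))
print(f"{len(corpus.documents)} documents, {len(corpus.gold)} gold spans")
for label, n in sorted(
    concept_span_counts(corpus.gold).items(), key=lambda kv: -kv[1]
):
    print(f"  {label.value:24s} {n:4d}")

span = next(s for s in corpus.gold if s.label is ConceptLabel.MEDICATION)
doc = corpus.doc_index()[span.doc_id]
print("\nexample medication span:", repr(span.raw_text))
print("in context:", repr(doc.text[max(0, span.start - 30) : span.end + 20]))
# The tally mirrors a realistic annotation corpus: mention frequency is
# heavily skewed, which is why rare concepts are harder to learn.
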