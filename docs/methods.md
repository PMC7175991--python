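# Methods

## Problem and data model

The package models a two-part feasibility problem: (1) given a patient's
structured record and free-text clinical notes, assemble the 17 predictors
of an OxMIS-style 12-month suicide risk model and score the patient even
when some predictors are unknown; (2) given annotated notes, train and
evaluate a named-entity extractor for the eight free-text concepts that
carry nine of those predictors (violence, self-harm, education,
medication, benefits, drug/alcohol use disorder, suicide, psychiatric
admission — medication covers both the antipsychotic and antidepressant
predictors).

Annotations are standoff: 0-based half-open character intervals
`[start, end)` against immutable document text, stored as JSON-lines
(document records, then span records). Each span carries a concept label
plus two attributes — `negated` and `experiencer` (patient / parent /
other) — defaulting to the modal annotation (affirmed, patient). The
format round-trips byte-identically, which the suite checks property-wise
over generated corpora.

## Document selection

Tokens (whitespace/punctuation split, lower-cased) are compared to
per-concept keyword lists by Levenshtein distance (edlib); a token matches
when distance ≤ `floor(f·len(keyword))` with `f = 0.2` by default. A
fractional budget rather than a fixed integer keeps short keywords strict.
A document's score is its count of matching tokens; selection takes the
top *k* by score with deterministic doc-id tie-breaks, so input order
never changes the chosen set.

## Extraction

The tagger is an averaged perceptron over BIO-encoded tokens with greedy
left-to-right decoding: features are the lower-cased word, 2–4 character
prefixes/suffixes, a collapsed orthographic shape, two words of context
either side, and the previous one/two predicted tags. Training shuffles
sequences with a seeded RNG and breaks score ties alphabetically, so the
entire train→predict path is deterministic given (corpus, seed). The
contract is the evaluation surface, not the architecture: any tagger
meeting the determinism and accuracy requirements could be substituted.

Phase-2 refinement consumes accept/reject judgments of the model's own
output: accepted spans supervise their tokens with their BIO tags,
rejected spans supervise theirs with O, and unjudged tokens carry no
supervision (no perceptron update). This reproduces an active-learning
accept/reject loop with plain continued training. `fine_tune` takes the
judged documents explicitly, since featurisation needs the text.

Negation is classic NegEx: pre-trigger phrases negate a span when the
trigger's last token is within `scope_window` (default 5) token steps
before the span in the same sentence; post-triggers work symmetrically;
pseudo-triggers ("no increase in") cancel a contained trigger. Sentence
boundaries are terminal punctuation + newline, and negation and
experiencer never cross them. Experiencer is a lexicon rule: a parental
term earlier in the sentence → parent; another third-party term → other;
else patient. Medication spans are grouped antipsychotic / antidepressant
/ other by case-insensitive longest-token lookup in a small bundled
glossary of ~45 generic psychotropic names (illustrative and
user-replaceable; a licensed formulary export is out of scope).

## Evaluation

Matching is one-to-one and greedy in gold start-offset order; ties go to
the longer predicted span. The default criterion is lenient overlap (any
character overlap, label must agree), with exact offsets available.
Negation/experiencer are deliberately ignored by matching — this is a
span-identification evaluation; attribute scoring would be a separate
report. Per concept: `missed = annotated − correct`, precision
`correct/(correct+spurious)`, recall `correct/annotated`, F1 harmonic
mean, zero denominators → 0. Micro-averaging pools raw counts across
concepts before dividing. Values are rounded half-up to 2 decimals only
at reporting.

## Variable assembly

Extracted spans become dated evidence events via a fixed mapping (e.g.
medication+antipsychotic → `antipsychotic_recent`; suicide with
experiencer=parent → `parental_suicide`; suicide about another third
party → no event; negated spans → absent polarity). Historical
predictors carry forward: one affirmed event at or before the reference
date makes the variable true at all later time-points, and absence
evidence never overrides an earlier affirmation (present-wins is also the
tie-break for same-day conflicts, which the original workflow leaves
unspecified). The two medication predictors are recency-bound with a
183-day window ("use in last 6 months"); stale-only present evidence
resolves to false rather than MISSING because it affirms non-recent use
(configurable in principle; false is the informative default).
Predictors with no events stay MISSING.

Parental variables support absence inference: when a patient's notes
contain at least `min_family_sentences` (default 3 — "extensive" is
inherently arbitrary, so it is a parameter) sentences mentioning family
members and a parental predictor has no evidence, it is assumed false.
Inference never overrides events.

Education is ordinal (secondary < upper-secondary < post-secondary),
resolved as the highest level among events carrying an explicit level.
Extracted education spans carry no level — sub-categorising education is
deliberately outside the extraction schema (a stage-2 attribute) — so
NLP-derived education stays MISSING and contributes to risk ranges;
structured or chart-review event sources may supply levels.

## Risk scoring

`risk = logistic(intercept + β_age·(age − age_ref) + Σ active-category
weights)`. Coefficients are a versioned JSON schema covering all 17
predictors (reference categories implicit at weight 0), so published
weights can be dropped in without code change; the bundled set is
explicitly illustrative. Missing predictors are handled by exhaustive
enumeration of the Cartesian product of their category domains (cap:
4 by default, configurable) — correct even for future coefficient sets
with interactions, and cheap at these domain sizes. Banding against the
cutoff (default 0.005/year): `low` if the whole range is below,
`increased` if even the minimum reaches the cutoff (a range touching the
cutoff at its low end counts as increased; exact-boundary behaviour is
otherwise undefined, so it is fixed and documented), `spanning`
otherwise.

## Synthetic data: what it emulates, and what it does not

The corpus generator writes template sentences with mentions embedded at
known offsets, giving exact gold spans by construction. It emulates the
features that matter to the pipeline: concept frequency skew matching a
realistic annotation corpus (medication ≫ self-harm ≫ … ≫ parental
suicide, normalised to 15 spans/1000 tokens); negated mentions (rate
0.10); parent/other attribution (suicide mentions mostly parental);
education phrased three ways (qualifications, institution, leaving age);
family-history paragraphs of ≥3 sentences; document dates spread over a
5-year window per patient to exercise carry-forward. A `vocab_overlap`
dial (default 0.2) draws that fraction of mentions from a shared word
pool that also appears in unlabelled filler text, tuning extractor
difficulty; `vocab_overlap=0` gives the disjoint-vocabulary "easy"
condition. Default size: 225 patients ≈ 1,350 documents ≈ 2,000 gold
spans.

It does **not** emulate real clinical language: no paraphrase beyond the
template inventory, no misspellings, no coreference, no clinical
plausibility of co-occurring variables, and per-1000-token densities are
calibrated only to relative proportions (true absolute densities are
unknown). High extractor scores here therefore bound the pipeline's
correctness, not its real-world accuracy; on real notes a held-out
micro-F1 near 0.8 is the realistic operating level, and the suite's
threshold on the default synthetic corpus is set at that level.

The cohort generator uses realistic marginals (60% male, age
N(47, 10.8²) clipped to [15, 65], 5% inpatient, 88% long first stay, 61%
>7 previous episodes, 32%/32% drug/alcohol abuse, 2% comorbid
depression). The evidence-event generator mimics a manual chart review:
definitive negatives are recorded as absent-polarity events, and exactly
four predictors (education 26%, benefits 25%, parental psychiatric
admission 16%, parental substance disorder 7%) can lack evidence
entirely, reproducing the observed missing-data pattern in which at most
4 of 17 predictors are unknown per patient.

The illustrative coefficient set jitters plausible log-odds magnitudes
(strongest: prior self-harm ≈ 0.9, parental suicide ≈ 0.7, inpatient ≈
0.8; small negative gradient for higher education; −0.012/year age) by
±20% per seed, then solves the intercept so the modal patient (male
outpatient on recent antipsychotics, long first stay, many episodes, on
benefits) has a fixed 0.4% 12-month risk. Anchoring the intercept rather
than randomising it keeps cohort risk distributions on the 0.1–1% order
of magnitude across seeds while the relative weight structure still
varies.

## Numerical and design choices

* Rounding half-up at 2 dp for reported metrics; full precision
  internally.
* `logistic` computed in the numerically stable branch form.
* Greedy matching ordered by gold start; longer-prediction tie-break;
  deterministic everywhere.
* Document-level 80/20 split for held-out evaluation (generator output
  order is already randomised).
* Overlapping gold spans of different labels are representable; the
  evaluator handles them since matching is per-label.
* Seeds: every stochastic component takes one integer seed; the pipeline
  derives per-stage seeds by fixed small offsets.

## Problem sizes

The test suite trains on a 40-patient disjoint-vocabulary corpus for the
extraction unit tests and on the full default corpora (~1,350 documents)
only in the end-to-end checks; the acceptance script runs both full
corpora plus the 57-patient cohort, completing in well under a minute on
one CPU. These sizes were chosen as the smallest that exercise every
code path at stable statistics.

## Known limitations

* The extractor is lexical; it will not generalise across genuinely
  novel phrasings the way a contextual-embedding model can.
* Experiencer attribution only looks left within a sentence; "suicide of
  the patient's father" (term after the span) would be missed.
* The evaluator treats negation as an attribute, not part of span
  identity; a negated gold span matched by an affirmed prediction counts
  correct at span level.
* Education level never comes from NLP in this version, only from
  structured/manual event sources.
* The bundled glossary and negation lexicon are small; production use
  should supply domain-curated replacements via the JSON loaders.
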