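# oxmisnlp

Tools for studying whether the predictors of a structured suicide risk
model can be recovered from routine mental-health records — and for
computing the risk scores once they are.

The target model is an OxMIS-style tool: a 17-predictor logistic model of
12-month suicide risk in severe mental illness (schizophrenia-spectrum and
bipolar disorders). Some predictors live in structured EHR fields (age,
sex, diagnosis codes, episode history); the rest are buried in free-text
clinical notes: previous self-harm, violent offending, recent
antipsychotic/antidepressant treatment, benefits receipt, highest
education, and three parental history variables. This package implements
the full pipeline around that problem, for NLP/epidemiology researchers
who want a tested, reproducible desk-side version of each stage:

* **synthetic data** — clinical-note corpora with exact gold annotations,
  structured cohorts and illustrative coefficient sets, so everything is
  runnable without access to any real EHR;
* **document selection** — Levenshtein fuzzy-keyword ranking to pick the
  most informative documents for annotation;
* **concept extraction** — a deterministic averaged-perceptron BIO tagger
  over eight risk-factor concepts, with NegEx-style negation, experiencer
  attribution (patient / parent / other) and medication-group mapping
  through a bundled formulary-style glossary;
* **evaluation** — span-level correct/spurious/missed counts and
  precision / recall / F1 per concept with micro-averaging:
  `P = TP/(TP+FP)`, `R = TP/gold`, `F1 = 2PR/(P+R)`, micro = pool counts,
  then divide;
* **variable assembly** — dated evidence events, historical carry-forward,
  a 6-month recency window for medication, and family-history absence
  inference for the parental variables;
* **risk scoring** — `risk = logistic(β₀ + β_age(age−age₀) + Σβ_active)`
  with pluggable JSON coefficients; when predictors are unknown the engine
  enumerates every completion and returns a `[min, max]` risk range,
  banded against a cutoff (default 0.5%/year) as low / increased /
  spanning.

## Worked example

```bash
python examples/04_risk_range_with_missing_data.py
```

```
12-month risk range across cohort: 0.16% - 2.95%
median risk: 0.69%
bands at 0.5% cutoff: {'low': 17, 'increased': 35, 'spanning': 5}

patient P0001: 2 missing predictor(s) -> risk [0.91%, 1.66%] over 6 completions, band=increased
```

A 57-patient synthetic cohort is assembled from structured fields plus
chart-review-style evidence events and scored with an illustrative
coefficient set: individual 12-month risks sit between roughly 0.1% and
3%, and each patient lands in exactly one band. A patient with two
unknown predictors gets a risk *range* — the min and max over all six
completions of the unknowns — rather than a point value.

The other examples (`examples/01..05`) cover corpus generation,
train/evaluate (printing the per-concept P/R/F1 table), the
negation/experiencer rules, and the end-to-end pipeline. Everything is
also exposed as a thin CLI:

```bash
oxmisnlp run --out runs/demo --seed 5
oxmisnlp evaluate --gold gold.jsonl --pred pred.jsonl --policy lenient --out report.csv
```

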