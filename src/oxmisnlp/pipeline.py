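"""End-to-end orchestration: generate → select → train → predict →
evaluate → assemble → score, with a single config and one seed.

Each stage writes its artifact into the run directory (standoff
predictions, evaluation report CSV, assembled-variables CSV, risk CSV) and
a manifest JSON records seeds, versions and per-stage counts, so two runs
with the same config and seed produce identical manifest counts.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .assembly import (
    assemble,
    carry_forward,
    cohort_to_csv,
    infer_family_absence,
    spans_to_events,
    variables_to_csv,
)
from .corpus import Corpus, write_standoff
from .evaluation import (
    MatchMode,
    MatchPolicy,
    evaluation_report,
    match_spans,
    micro_average,
)
from .extraction import ExtractorModel, predict_corpus, train
from .scoring import risk_range
from .selection import default_keyword_set, select_top
from .synthetic import (
    GeneratorConfig,
    generate_cohort,
    generate_coefficients,
    generate_corpus,
)

logger = logging.getLogger("oxmisnlp.pipeline")


@dataclass
class PipelineConfig:
    """Configuration of a full run; JSON-loadable."""

    out_dir: Union[str, Path] = "runs/demo"
    seed: int = 0
    n_patients: int = 225
    split_fraction: float = 0.8  # document-level train share
    match_mode: MatchMode = MatchMode.LENIENT_OVERLAP
    cutoff: float = 0.005
    recency_window_days: int = 183
    min_family_sentences: int = 3
    reference_date: _dt.date = _dt.date(2019, 12, 31)
    select_top_k: Optional[int] = None  # None = train on the whole train split
    max_missing: int = 9  # range-enumeration cap for NLP-derived vectors
    train_model: bool = True
    model_path: Optional[Union[str, Path]] = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        kwargs = dict(data)
        if "match_mode" in kwargs:
            kwargs["match_mode"] = MatchMode(kwargs["match_mode"])
        if "reference_date" in kwargs:
            kwargs["reference_date"] = _dt.date.fromisoformat(
                kwargs["reference_date"]
            )
        generator = kwargs.pop("generator", {})
        config = cls(**kwargs)
        if generator:
            config.generator = replace(GeneratorConfig(), **generator)
        return config


def split_corpus(corpus: Corpus, fraction: float) -> tuple[Corpus, Corpus]:
    """Document-level split: the first ``fraction`` of documents (in corpus
    order, which the generator already randomised) train, the rest test."""
    n_train = int(len(corpus.documents) * fraction)
    train_docs = corpus.documents[:n_train]
    test_docs = corpus.documents[n_train:]
    train_ids = {d.doc_id for d in train_docs}
    return (
        Corpus(train_docs, [s for s in corpus.gold if s.doc_id in train_ids]),
        Corpus(test_docs, [s for s in corpus.gold if s.doc_id not in train_ids]),
    )


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    # --- generate ---------------------------------------------------------
    generator = replace(
        config.generator, seed=config.seed, n_patients=config.n_patients
    )
    corpus = generate_corpus(generator)
    cohort = generate_cohort(config.n_patients, seed=config.seed + 1)
    coeffs = generate_coefficients(seed=config.seed + 2)
    write_standoff(corpus, out / "corpus.jsonl")
    cohort_to_csv(cohort, out / "cohort.csv")
    coeffs.to_json(out / "coefficients.json")
    logger.info(
        "generate: %d documents, %d gold spans, %d patients",
        len(corpus.documents),
        len(corpus.gold),
        len(cohort),
    )
    manifest["stages"]["generate"] = {
        "documents": len(corpus.documents),
        "gold_spans": len(corpus.gold),
        "patients": len(cohort),
    }

    # --- split / select ---------------------------------------------------
    train_corpus, test_corpus = split_corpus(corpus, config.split_fraction)
    if config.select_top_k is not None:
        keywords = default_keyword_set()
        selected = set(
            select_top(train_corpus, keywords, config.select_top_k)
        )
        train_corpus = Corpus(
            [d for d in train_corpus.documents if d.doc_id in selected],
            [s for s in train_corpus.gold if s.doc_id in selected],
        )
    manifest["stages"]["select"] = {
        "train_documents": len(train_corpus.documents),
        "test_documents": len(test_corpus.documents),
        "train_spans": len(train_corpus.gold),
        "test_spans": len(test_corpus.gold),
    }

    # --- train ------------------------------------------------------------
    if config.train_model:
        model = train(train_corpus, seed=config.seed)
        model.save(out / "model.json")
    else:
        if config.model_path is None:
            raise ValueError("train_model=False requires model_path")
        model = ExtractorModel.load(config.model_path)
    manifest["stages"]["train"] = {
        "phase": model.phase,
        "n_training_spans": model.n_training_spans,
        "trained": config.train_model,
    }

    # --- predict ----------------------------------------------------------
    predicted = predict_corpus(model, test_corpus)
    pred_corpus = Corpus(test_corpus.documents, predicted)
    write_standoff(pred_corpus, out / "predictions.jsonl")
    manifest["stages"]["predict"] = {"predicted_spans": len(predicted)}

    # --- evaluate ---------------------------------------------------------
    counts = match_spans(
        test_corpus.gold, predicted, MatchPolicy(mode=config.match_mode)
    )
    evaluation_report(counts, out / "evaluation.csv")
    micro = micro_average(list(counts.values()))
    logger.info(
        "evaluate: micro P=%.3f R=%.3f F1=%.3f",
        micro.precision,
        micro.recall,
        micro.f1,
    )
    manifest["stages"]["evaluate"] = {
        "micro_precision": round(micro.precision, 4),
        "micro_recall": round(micro.recall, 4),
        "micro_f1": round(micro.f1, 4),
    }

    # --- assemble ---------------------------------------------------------
    # deploy the extractor over every note, then resolve predictors
    all_predicted = predict_corpus(model, corpus)
    events = spans_to_events(all_predicted, corpus.documents)
    manifest["stages"]["assemble_events"] = {"events": len(events)}
    partials = carry_forward(
        events, config.reference_date, config.recency_window_days
    )
    partials = infer_family_absence(
        corpus.documents, partials, config.min_family_sentences
    )
    variables = []
    for record in cohort:
        variables.append(assemble(record, partials.get(record.patient_id)))
    variables_to_csv(variables, out / "variables.csv")
    n_missing = sum(len(v.missing_predictors()) for v in variables)
    manifest["stages"]["assemble"] = {
        "patients": len(variables),
        "missing_slots": n_missing,
    }

    # --- score ------------------------------------------------------------
    rows = []
    for v in variables:
        result = risk_range(
            v, coeffs, cutoff=config.cutoff, max_missing=config.max_missing
        )
        rows.append(
            {
                "patient_id": v.patient_id,
                "low": result.low,
                "high": result.high,
                "band": result.band.value,
                "completions_evaluated": result.completions_evaluated,
            }
        )
    pd.DataFrame(rows).to_csv(out / "risk.csv", index=False)
    bands = pd.Series([r["band"] for r in rows]).value_counts().to_dict()
    manifest["stages"]["score"] = {
        "patients": len(rows),
        "bands": {k: int(v) for k, v in sorted(bands.items())},
    }

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return manifest
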