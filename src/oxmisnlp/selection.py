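"""Fuzzy-keyword document ranking for annotation triage.

Annotator time is the scarce resource when building a gold corpus, so
documents are ranked by how many of their tokens approximately match a
predefined per-concept keyword list, and the top-scoring documents are
selected for annotation.  Approximate matching is Levenshtein distance
(via edlib) with a budget proportional to keyword length, so short
keywords stay strict while longer ones tolerate typos and spelling
variants ("selfharm" vs "self-harm").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import edlib

from .corpus import ConceptLabel, Corpus, Document
from .text import word_tokens


@dataclass(frozen=True)
class KeywordSet:
    """Per-concept keyword lists plus the edit-distance budget fraction.

    A token matches a keyword when their Levenshtein distance is at most
    ``floor(max_edit_distance_fraction * len(keyword))``.
    """

    keywords: dict = field(default_factory=dict)
    max_edit_distance_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("keyword set must not be empty")
        if not (0.0 <= self.max_edit_distance_fraction <= 1.0):
            raise ValueError("max_edit_distance_fraction must be in [0, 1]")
        normalised: dict[ConceptLabel, tuple[str, ...]] = {}
        for label, words in self.keywords.items():
            label = ConceptLabel(label)
            cleaned = tuple(w.lower() for w in words)
            if not cleaned or any(not w for w in cleaned):
                raise ValueError(f"concept {label.value!r} needs non-empty keywords")
            normalised[label] = cleaned
        object.__setattr__(self, "keywords", normalised)

    def all_keywords(self) -> list[str]:
        return [w for words in self.keywords.values() for w in words]

    @classmethod
    def from_json(
        cls, path: Union[str, Path], max_edit_distance_fraction: float = 0.2
    ) -> "KeywordSet":
        return cls(
            keywords=json.loads(Path(path).read_text(encoding="utf-8")),
            max_edit_distance_fraction=max_edit_distance_fraction,
        )


#: hand-picked default keywords per concept, the usual starting point for
#: annotation triage; callers with domain keyword lists should supply their own.
DEFAULT_KEYWORDS: dict[str, list[str]] = {
    "violence": ["assault", "violence", "violent", "conviction", "affray"],
    "self_harm": ["self-harm", "selfharm", "overdose", "cutting"],
    "education": ["school", "gcse", "university", "college", "education"],
    "medication": ["olanzapine", "risperidone", "quetiapine", "clozapine",
                   "sertraline", "fluoxetine", "mirtazapine", "medication"],
    "benefits": ["benefit", "benefits", "pip", "esa", "universal"],
    "substance_use_disorder": ["alcohol", "cannabis", "opiate", "dependence",
                               "drinking"],
    "suicide": ["suicide"],
    "psychiatric_admission": ["admission", "admitted", "sectioned", "ward"],
}


def default_keyword_set(max_edit_distance_fraction: float = 0.2) -> KeywordSet:
    return KeywordSet(
        keywords=DEFAULT_KEYWORDS,
        max_edit_distance_fraction=max_edit_distance_fraction,
    )


def _distance(a: str, b: str, limit: int) -> int:
    """Levenshtein distance, -1 if it exceeds ``limit``."""
    if abs(len(a) - len(b)) > limit:
        return -1
    return edlib.align(a, b, task="distance", k=limit)["editDistance"]


def token_matches(token: str, keyword: str, fraction: float) -> bool:
    budget = int(fraction * len(keyword))
    return _distance(token, keyword, budget) != -1


def score_document(doc: Document, keywords: KeywordSet) -> int:
    """Count of document tokens fuzzily matching any keyword.

    Monotone by construction: appending an exact keyword occurrence adds a
    matching token and never removes one.
    """
    fraction = keywords.max_edit_distance_fraction
    vocabulary = keywords.all_keywords()
    score = 0
    for token in word_tokens(doc.text):
        if any(token_matches(token, kw, fraction) for kw in vocabulary):
            score += 1
    return score


def select_top(corpus: Corpus, keywords: KeywordSet, k: int) -> list[str]:
    """Ids of the top-``k`` documents by keyword score.

    Non-increasing score order, ties broken by doc_id so the selection is
    independent of input document order.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    scored = sorted(
        ((score_document(doc, keywords), doc.doc_id) for doc in corpus.documents),
        key=lambda pair: (-pair[0], pair[1]),
    )
    return [doc_id for _, doc_id in scored[:k]]
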