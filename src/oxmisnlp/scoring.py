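"""12-month suicide risk from the 17-predictor vector.

The engine is a plain logistic model: risk = logistic(intercept + age
weight x (age - reference age) + one weight per active non-reference
category).  Coefficients are pluggable through a versioned JSON schema so a
published coefficient set can be dropped in without code change; the set
bundled with the synthetic-data generator is illustrative, not the
published OxMIS weights.

When predictors are MISSING, the engine enumerates every completion of the
missing slots exhaustively and reports the minimum and maximum risk over
completions — a risk *range* instead of a point estimate — then bands the
result against a cutoff (default 0.5% in 12 months): ``low`` when the whole
range sits below the cutoff, ``increased`` when the low end reaches it,
``spanning`` when the range straddles it.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Union

from .assembly import EducationLevel, EpisodeType, OxMISVariables, Sex

COEFFICIENT_SCHEMA_VERSION = 1

# categorical domain of every non-age predictor; first entry = reference
PREDICTOR_CATEGORIES: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "current_episode": ("outpatient", "inpatient"),
    "first_stay_gt7days": ("false", "true"),
    "previous_episodes_gt7": ("false", "true"),
    "drug_abuse": ("false", "true"),
    "alcohol_abuse": ("false", "true"),
    "comorbid_depression": ("false", "true"),
    "violent_crime": ("false", "true"),
    "self_harm": ("false", "true"),
    "antipsychotic_recent": ("false", "true"),
    "antidepressant_recent": ("false", "true"),
    "benefits": ("false", "true"),
    "education": ("secondary", "upper_secondary", "post_secondary"),
    "parental_psych_admission": ("false", "true"),
    "parental_substance_disorder": ("false", "true"),
    "parental_suicide": ("false", "true"),
}


class RiskBand(str, Enum):
    LOW = "low"
    INCREASED = "increased"
    SPANNING = "spanning"


@dataclass(frozen=True)
class CoefficientSet:
    """Versioned log-odds weights over all 17 predictors.

    ``predictors`` maps each categorical predictor to per-category weights
    (the reference category may be omitted and counts as 0); age enters
    linearly with ``age_weight`` per year, centred at ``age_reference``.
    """

    name: str
    version: int
    intercept: float
    age_weight: float
    age_reference: float
    predictors: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for predictor, categories in PREDICTOR_CATEGORIES.items():
            if predictor not in self.predictors:
                raise ValueError(f"coefficient set missing predictor {predictor!r}")
            for category in self.predictors[predictor]:
                if category not in categories:
                    raise ValueError(
                        f"unknown category {category!r} for predictor {predictor!r}"
                    )
        for weights in self.predictors.values():
            for w in weights.values():
                if not math.isfinite(w):
                    raise ValueError("coefficient weights must be finite")
        if not (
            math.isfinite(self.intercept) and math.isfinite(self.age_weight)
        ):
            raise ValueError("intercept and age weight must be finite")

    def weight(self, predictor: str, category: str) -> float:
        return self.predictors[predictor].get(category, 0.0)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CoefficientSet":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            name=data["name"],
            version=int(data["version"]),
            intercept=float(data["intercept"]),
            age_weight=float(data["age"]["weight"]),
            age_reference=float(data["age"]["reference"]),
            predictors={
                p: {c: float(w) for c, w in cats.items()}
                for p, cats in data["predictors"].items()
            },
        )

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "name": self.name,
                    "version": self.version,
                    "intercept": self.intercept,
                    "age": {
                        "weight": self.age_weight,
                        "reference": self.age_reference,
                    },
                    "predictors": self.predictors,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n",
            encoding="utf-8",
        )


@dataclass(frozen=True)
class RiskResult:
    """A 12-month risk point value or [low, high] range, plus its band."""

    low: float
    high: float
    band: RiskBand
    completions_evaluated: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.low <= self.high <= 1.0):
            raise ValueError("risk range must satisfy 0 <= low <= high <= 1")

    @property
    def is_point(self) -> bool:
        return self.completions_evaluated == 1


def logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def _category_of(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (Sex, EpisodeType, EducationLevel)):
        return value.value
    raise TypeError(f"cannot express {value!r} as a predictor category")


def point_risk(vars: OxMISVariables, coeffs: CoefficientSet) -> float:
    """Risk for a complete vector; raises if any predictor is MISSING."""
    missing = vars.missing_predictors()
    if missing:
        raise ValueError(
            f"vector has MISSING predictors {missing}; use risk_range instead"
        )
    lp = coeffs.intercept + coeffs.age_weight * (vars.age - coeffs.age_reference)
    for predictor in PREDICTOR_CATEGORIES:
        lp += coeffs.weight(predictor, _category_of(getattr(vars, predictor)))
    return logistic(lp)


def _completion_values(predictor: str):
    categories = PREDICTOR_CATEGORIES[predictor]
    if predictor == "education":
        return tuple(EducationLevel(c) for c in categories)
    return tuple(c == "true" for c in categories)


def risk_range(
    vars: OxMISVariables,
    coeffs: CoefficientSet,
    cutoff: float = 0.005,
    max_missing: int = 4,
) -> RiskResult:
    """Min-max risk over every completion of the MISSING predictors.

    Enumerates the Cartesian product of the missing predictors' category
    domains (exhaustive, so correct even for coefficient sets with
    interactions); with no MISSING predictors this degenerates to the point
    estimate.  ``max_missing`` caps the enumeration.
    """
    missing = vars.missing_predictors()
    if len(missing) > max_missing:
        raise ValueError(
            f"{len(missing)} predictors are MISSING, exceeding the cap of "
            f"{max_missing}: {missing}"
        )
    domains = [_completion_values(name) for name in missing]
    risks: list[float] = []
    for combo in itertools.product(*domains):
        completed = OxMISVariables(**vars.as_completion(dict(zip(missing, combo))))
        risks.append(point_risk(completed, coeffs))
    low, high = min(risks), max(risks)
    return RiskResult(
        low=low,
        high=high,
        band=classify_range(low, high, cutoff),
        completions_evaluated=len(risks),
    )


def classify_range(low: float, high: float, cutoff: float = 0.005) -> RiskBand:
    """Band a risk range against the cutoff.

    ``low`` band when the whole range is below the cutoff; ``increased``
    when even the minimum reaches it (a range touching the cutoff at its
    low end counts as increased); ``spanning`` when the range straddles it.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must be in (0, 1)")
    if high < cutoff:
        return RiskBand.LOW
    if low >= cutoff:
        return RiskBand.INCREASED
    return RiskBand.SPANNING


def classify(result: RiskResult, cutoff: float = 0.005) -> RiskBand:
    return classify_range(result.low, result.high, cutoff)
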