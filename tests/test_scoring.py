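"""Logistic risk engine: point risks, missing-data ranges, banding."""

import itertools
import math
import random

import pytest

from oxmisnlp.assembly import (
    MISSING,
    EducationLevel,
    EpisodeType,
    OxMISVariables,
    Sex,
)
from oxmisnlp.scoring import (
    PREDICTOR_CATEGORIES,
    CoefficientSet,
    RiskBand,
    classify_range,
    logistic,
    point_risk,
    risk_range,
)
from oxmisnlp.synthetic import generate_coefficients


def flat_coeffs(**overrides) -> CoefficientSet:
    """A hand-auditable coefficient set; unspecified weights are zero."""
    predictors = {name: {} for name in PREDICTOR_CATEGORIES}
    for name, weights in overrides.pop("predictors", {}).items():
        predictors[name] = weights
    return CoefficientSet(
        name="fixture",
        version=1,
        intercept=overrides.pop("intercept", -5.0),
        age_weight=overrides.pop("age_weight", 0.0),
        age_reference=overrides.pop("age_reference", 47.0),
        predictors=predictors,
    )


def reference_vector(**overrides) -> OxMISVariables:
    defaults = dict(
        patient_id="p1",
        age=47.0,
        sex=Sex.FEMALE,
        current_episode=EpisodeType.OUTPATIENT,
        first_stay_gt7days=False,
        previous_episodes_gt7=False,
        drug_abuse=False,
        alcohol_abuse=False,
        comorbid_depression=False,
        violent_crime=False,
        self_harm=False,
        antipsychotic_recent=False,
        antidepressant_recent=False,
        benefits=False,
        education=EducationLevel.SECONDARY,
        parental_psych_admission=False,
        parental_substance_disorder=False,
        parental_suicide=False,
    )
    defaults.update(overrides)
    return OxMISVariables(**defaults)


def test_reference_vector_risk_is_logistic_intercept():
    coeffs = flat_coeffs(intercept=-5.0)
    assert point_risk(reference_vector(), coeffs) == pytest.approx(
        logistic(-5.0)
    )


def test_point_risk_matches_hand_computed_log_odds():
    coeffs = flat_coeffs(
        intercept=-6.0,
        age_weight=-0.01,
        predictors={
            "sex": {"male": 0.4},
            "self_harm": {"true": 0.9},
            "education": {"post_secondary": -0.3},
        },
    )
    v = reference_vector(
        sex=Sex.MALE,
        self_harm=True,
        education=EducationLevel.POST_SECONDARY,
        age=57.0,
    )
    expected = 1.0 / (1.0 + math.exp(-(-6.0 + 0.4 + 0.9 - 0.3 - 0.01 * 10)))
    assert point_risk(v, coeffs) == pytest.approx(expected)


def test_positive_weight_flip_strictly_increases_risk():
    coeffs = flat_coeffs(predictors={"parental_suicide": {"true": 0.7}})
    low = point_risk(reference_vector(), coeffs)
    high = point_risk(reference_vector(parental_suicide=True), coeffs)
    assert high > low


def test_point_risk_rejects_missing():
    with pytest.raises(ValueError, match="risk_range"):
        point_risk(reference_vector(benefits=MISSING), flat_coeffs())


def test_degenerate_range_equals_point_risk():
    coeffs = flat_coeffs()
    v = reference_vector()
    result = risk_range(v, coeffs)
    assert result.completions_evaluated == 1
    assert result.low == result.high == point_risk(v, coeffs)


def test_one_missing_binary_matches_both_completions():
    coeffs = flat_coeffs(predictors={"benefits": {"true": 0.2}})
    v = reference_vector(benefits=MISSING)
    result = risk_range(v, coeffs)
    risks = sorted(
        point_risk(reference_vector(benefits=b), coeffs) for b in (False, True)
    )
    assert result.completions_evaluated == 2
    assert (result.low, result.high) == (risks[0], risks[-1])


def test_two_missing_match_exhaustive_enumeration():
    coeffs = flat_coeffs(
        predictors={
            "benefits": {"true": 0.2},
            "education": {"upper_secondary": -0.1, "post_secondary": -0.3},
        }
    )
    v = reference_vector(benefits=MISSING, education=MISSING)
    result = risk_range(v, coeffs)
    risks = [
        point_risk(reference_vector(benefits=b, education=e), coeffs)
        for b in (False, True)
        for e in EducationLevel
    ]
    assert result.completions_evaluated == 6
    assert result.low == pytest.approx(min(risks))
    assert result.high == pytest.approx(max(risks))


def test_missing_cap_enforced():
    v = reference_vector(
        benefits=MISSING,
        education=MISSING,
        self_harm=MISSING,
        violent_crime=MISSING,
        parental_suicide=MISSING,
    )
    with pytest.raises(ValueError, match="cap"):
        risk_range(v, flat_coeffs(), max_missing=4)


MISSABLE = [
    "violent_crime",
    "self_harm",
    "antipsychotic_recent",
    "antidepressant_recent",
    "benefits",
    "education",
    "parental_psych_admission",
    "parental_substance_disorder",
    "parental_suicide",
]


def random_partial_vector(rng: random.Random) -> OxMISVariables:
    overrides = {
        "age": rng.uniform(15, 65),
        "sex": rng.choice(list(Sex)),
        "current_episode": rng.choice(list(EpisodeType)),
    }
    for name in (
        "first_stay_gt7days",
        "previous_episodes_gt7",
        "drug_abuse",
        "alcohol_abuse",
        "comorbid_depression",
    ):
        overrides[name] = rng.random() < 0.5
    for name in MISSABLE:
        if name == "education":
            overrides[name] = rng.choice(list(EducationLevel))
        else:
            overrides[name] = rng.random() < 0.5
    for name in rng.sample(MISSABLE, rng.randint(0, 4)):
        overrides[name] = MISSING
    return reference_vector(**overrides)


def brute_force_range(v: OxMISVariables, coeffs: CoefficientSet):
    """Independent enumeration oracle over all completions."""
    missing = v.missing_predictors()
    domains = []
    for name in missing:
        if name == "education":
            domains.append(list(EducationLevel))
        else:
            domains.append([False, True])
    risks = []
    for combo in itertools.product(*domains):
        kwargs = {name: getattr(v, name) for name in v.PREDICTORS}
        kwargs.update(dict(zip(missing, combo)))
        kwargs["patient_id"] = v.patient_id
        risks.append(point_risk(OxMISVariables(**kwargs), coeffs))
    return min(risks), max(risks), len(risks)


def test_range_agrees_with_brute_force_on_200_random_vectors():
    rng = random.Random(42)
    coeffs = generate_coefficients(seed=4)
    for _ in range(200):
        v = random_partial_vector(rng)
        result = risk_range(v, coeffs)
        lo, hi, n = brute_force_range(v, coeffs)
        assert result.low == pytest.approx(lo)
        assert result.high == pytest.approx(hi)
        assert result.completions_evaluated == n
        # enumeration-count law
        expected_n = 1
        for name in v.missing_predictors():
            expected_n *= 3 if name == "education" else 2
        assert n == expected_n
        # containment of random full completions
        for _ in range(3):
            kwargs = {name: getattr(v, name) for name in v.PREDICTORS}
            for name in v.missing_predictors():
                kwargs[name] = (
                    rng.choice(list(EducationLevel))
                    if name == "education"
                    else rng.random() < 0.5
                )
            kwargs["patient_id"] = v.patient_id
            r = point_risk(OxMISVariables(**kwargs), coeffs)
            assert result.low - 1e-12 <= r <= result.high + 1e-12


@pytest.mark.parametrize(
    "low,high,band",
    [
        (0.002, 0.004, RiskBand.LOW),
        (0.006, 0.012, RiskBand.INCREASED),
        (0.004, 0.007, RiskBand.SPANNING),
        (0.005, 0.009, RiskBand.INCREASED),  # touching at the low end
    ],
)
def test_classification_bands(low, high, band):
    assert classify_range(low, high, cutoff=0.005) is band


def test_generated_coefficients_are_valid_and_anchored():
    c1 = generate_coefficients(seed=9)
    c2 = generate_coefficients(seed=9)
    assert c1 == c2
    # the all-reference vector at the reference age is the closed form
    assert point_risk(reference_vector(sex=Sex.FEMALE), c1) == pytest.approx(
        logistic(c1.intercept)
    )


def test_coefficient_json_roundtrip(tmp_path):
    coeffs = generate_coefficients(seed=2)
    path = tmp_path / "coeffs.json"
    coeffs.to_json(path)
    assert CoefficientSet.from_json(path) == coeffs


def test_coefficient_set_requires_all_predictors():
    with pytest.raises(ValueError, match="missing predictor"):
        CoefficientSet(
            name="bad",
            version=1,
            intercept=-5.0,
            age_weight=0.0,
            age_reference=47.0,
            predictors={"sex": {"male": 0.1}},
        )
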