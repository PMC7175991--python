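"""Bundled lexicons: negation triggers, family terms, medication glossary.

All three are deliberately small, illustrative and user-replaceable (each
has a JSON loader).  The negation lexicon follows the classic NegEx design:
pre-span and post-span trigger phrases, pseudo-triggers that cancel a
match, and a token scope window.  The medication glossary maps generic drug
names to the three groups used for predictor assembly (antipsychotic,
antidepressant, other); it is a short extract in the spirit of a national
formulary grouping, not a licensed copy of one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union


@dataclass(frozen=True)
class NegationLexicon:
    """Trigger phrases and scope for rule-based negation detection."""

    pre_triggers: tuple[str, ...]
    post_triggers: tuple[str, ...]
    pseudo_triggers: tuple[str, ...]
    scope_window: int = 5

    def __post_init__(self) -> None:
        if self.scope_window < 1:
            raise ValueError("scope_window must be >= 1")
        pre, post, pseudo = (
            set(self.pre_triggers),
            set(self.post_triggers),
            set(self.pseudo_triggers),
        )
        if pre & post or pre & pseudo or post & pseudo:
            raise ValueError("trigger lists must be disjoint")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "NegationLexicon":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            pre_triggers=tuple(data["pre_triggers"]),
            post_triggers=tuple(data["post_triggers"]),
            pseudo_triggers=tuple(data["pseudo_triggers"]),
            scope_window=int(data.get("scope_window", 5)),
        )

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "pre_triggers": list(self.pre_triggers),
                    "post_triggers": list(self.post_triggers),
                    "pseudo_triggers": list(self.pseudo_triggers),
                    "scope_window": self.scope_window,
                },
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )


DEFAULT_NEGATION_LEXICON = NegationLexicon(
    pre_triggers=(
        "no",
        "not",
        "never",
        "denies",
        "denied",
        "without",
        "stopped",
        "stopped taking",
        "discontinued",
        "ceased",
        "no history of",
        "no evidence of",
        "no longer",
        "declined",
        "refused",
        "off",
        "free of",
        "absence of",
        "negative for",
    ),
    post_triggers=(
        "was ruled out",
        "ruled out",
        "unlikely",
        "was discontinued",
        "was stopped",
        "has been discontinued",
    ),
    pseudo_triggers=(
        "no increase in",
        "no change in",
        "not only",
        "no further",
        "not certain if",
    ),
    scope_window=5,
)


# family terms: "parent" category feeds the three parental predictors;
# "other" covers non-parent third parties who never map to a predictor.
PARENT_TERMS: tuple[str, ...] = (
    "mother",
    "father",
    "parent",
    "parents",
    "mum",
    "dad",
    "mom",
    "stepmother",
    "stepfather",
    "maternal",
    "paternal",
)

OTHER_PERSON_TERMS: tuple[str, ...] = (
    "brother",
    "sister",
    "sibling",
    "siblings",
    "uncle",
    "aunt",
    "cousin",
    "grandmother",
    "grandfather",
    "friend",
    "flatmate",
    "neighbour",
    "partner",
    "wife",
    "husband",
    "son",
    "daughter",
)

# family-history sentence detector uses the union
FAMILY_TERMS: tuple[str, ...] = PARENT_TERMS + OTHER_PERSON_TERMS


@dataclass(frozen=True)
class MedicationGlossary:
    """Case-insensitive drug-name -> group lookup; unknown names -> 'other'."""

    mapping: dict = field(default_factory=dict)

    GROUPS = ("antipsychotic", "antidepressant", "other")

    def __post_init__(self) -> None:
        normalised = {k.lower(): v for k, v in self.mapping.items()}
        for name, group in normalised.items():
            if group not in self.GROUPS:
                raise ValueError(f"unknown medication group {group!r} for {name!r}")
        object.__setattr__(self, "mapping", normalised)

    def lookup(self, name: str) -> str:
        return self.mapping.get(name.lower(), "other")

    def __contains__(self, name: str) -> bool:
        return name.lower() in self.mapping

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "MedicationGlossary":
        return cls(mapping=json.loads(Path(path).read_text(encoding="utf-8")))

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(self.mapping, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


_ANTIPSYCHOTICS = (
    "olanzapine",
    "risperidone",
    "quetiapine",
    "aripiprazole",
    "clozapine",
    "haloperidol",
    "amisulpride",
    "paliperidone",
    "lurasidone",
    "chlorpromazine",
    "flupentixol",
    "zuclopenthixol",
    "sulpiride",
    "trifluoperazine",
    "cariprazine",
    "pimozide",
    "levomepromazine",
    "asenapine",
)

_ANTIDEPRESSANTS = (
    "sertraline",
    "fluoxetine",
    "citalopram",
    "escitalopram",
    "paroxetine",
    "venlafaxine",
    "duloxetine",
    "mirtazapine",
    "amitriptyline",
    "nortriptyline",
    "clomipramine",
    "lofepramine",
    "trazodone",
    "vortioxetine",
    "agomelatine",
    "phenelzine",
    "moclobemide",
    "reboxetine",
)

_OTHER_PSYCHOTROPICS = (
    "lithium",
    "sodium valproate",
    "lamotrigine",
    "carbamazepine",
    "diazepam",
    "lorazepam",
    "zopiclone",
    "promethazine",
    "pregabalin",
    "procyclidine",
)

DEFAULT_MEDICATION_GLOSSARY = MedicationGlossary(
    mapping={
        **{name: "antipsychotic" for name in _ANTIPSYCHOTICS},
        **{name: "antidepressant" for name in _ANTIDEPRESSANTS},
        **{name: "other" for name in _OTHER_PSYCHOTROPICS},
    }
)
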