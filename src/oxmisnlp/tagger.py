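"""Averaged-perceptron sequence tagger over BIO-encoded concept labels.

A deliberately transparent, dependency-free tagger: multiclass perceptron
with greedy left-to-right decoding, the previous predicted tag fed back as
a feature, and weight averaging over all updates for stability.  Features
are lexical and orthographic (word identity, lower-case form, prefixes,
suffixes, shape, neighbouring words).  Training is fully deterministic
given the seed: examples are shuffled with a seeded RNG and ties in
argmax are broken alphabetically by tag.

The tagger supports continued training on additional (possibly partially
labelled) sequences, which is how accept/reject fine-tuning is realised:
``None`` reference tags mean "no supervision at this token" and never
trigger an update.
"""

from __future__ import annotations

import random
from collections import defaultdict
from typing import Optional, Sequence


def word_shape(word: str) -> str:
    shape = []
    for ch in word[:8]:
        if ch.isupper():
            shape.append("X")
        elif ch.islower():
            shape.append("x")
        elif ch.isdigit():
            shape.append("d")
        else:
            shape.append(ch)
    # collapse runs to keep the feature space small
    collapsed = []
    for ch in shape:
        if not collapsed or collapsed[-1] != ch:
            collapsed.append(ch)
    return "".join(collapsed)


def token_features(
    words: Sequence[str], i: int, prev_tag: str, prev2_tag: str
) -> list[str]:
    w = words[i]
    lower = w.lower()
    prev_w = words[i - 1].lower() if i > 0 else "<s>"
    prev2_w = words[i - 2].lower() if i > 1 else "<s>"
    next_w = words[i + 1].lower() if i + 1 < len(words) else "</s>"
    next2_w = words[i + 2].lower() if i + 2 < len(words) else "</s>"
    return [
        "bias",
        f"w={lower}",
        f"suf3={lower[-3:]}",
        f"suf4={lower[-4:]}",
        f"pre2={lower[:2]}",
        f"pre3={lower[:3]}",
        f"shape={word_shape(w)}",
        f"prev={prev_w}",
        f"prev2={prev2_w}",
        f"next={next_w}",
        f"next2={next2_w}",
        f"prev+w={prev_w}+{lower}",
        f"w+next={lower}+{next_w}",
        f"ptag={prev_tag}",
        f"ptag2={prev2_tag}",
        f"ptag+w={prev_tag}+{lower}",
    ]


class AveragedPerceptron:
    """Sparse multiclass perceptron with lazily-averaged weights."""

    def __init__(self, tags: Sequence[str]):
        self.tags = sorted(tags)
        self.weights: dict[str, dict[str, float]] = {}
        self._totals: dict[tuple[str, str], float] = defaultdict(float)
        self._stamps: dict[tuple[str, str], int] = defaultdict(int)
        self._updates = 0
        self._averaged: Optional[dict[str, dict[str, float]]] = None

    def score(self, features: Sequence[str], weights=None) -> dict[str, float]:
        weights = weights if weights is not None else self.weights
        scores = dict.fromkeys(self.tags, 0.0)
        for feat in features:
            per_tag = weights.get(feat)
            if not per_tag:
                continue
            for tag, weight in per_tag.items():
                scores[tag] += weight
        return scores

    def predict(self, features: Sequence[str], averaged: bool = True) -> str:
        weights = self._averaged if (averaged and self._averaged) else self.weights
        scores = self.score(features, weights)
        # self.tags is sorted, and max keeps the first maximum, so score
        # ties resolve alphabetically — decoding is deterministic
        return max(self.tags, key=scores.__getitem__)

    def update(self, truth: str, guess: str, features: Sequence[str]) -> None:
        self._updates += 1
        if truth == guess:
            return
        for feat in features:
            per_tag = self.weights.setdefault(feat, {})
            for tag, delta in ((truth, 1.0), (guess, -1.0)):
                key = (feat, tag)
                self._totals[key] += (
                    self._updates - self._stamps[key]
                ) * per_tag.get(tag, 0.0)
                self._stamps[key] = self._updates
                per_tag[tag] = per_tag.get(tag, 0.0) + delta
        self._averaged = None

    def finalize(self) -> None:
        """Compute the averaged weights used at prediction time."""
        averaged: dict[str, dict[str, float]] = {}
        for feat, per_tag in self.weights.items():
            for tag, weight in per_tag.items():
                key = (feat, tag)
                total = self._totals[key] + (
                    self._updates - self._stamps[key]
                ) * weight
                if self._updates:
                    value = total / self._updates
                else:
                    value = weight
                if value:
                    averaged.setdefault(feat, {})[tag] = value
        self._averaged = averaged

    def to_dict(self) -> dict:
        if self._averaged is None:
            self.finalize()
        return {"tags": self.tags, "weights": self._averaged}

    @classmethod
    def from_dict(cls, data: dict) -> "AveragedPerceptron":
        model = cls(tags=data["tags"])
        model._averaged = {
            feat: dict(per_tag) for feat, per_tag in data["weights"].items()
        }
        model.weights = {
            feat: dict(per_tag) for feat, per_tag in model._averaged.items()
        }
        return model


TaggedSequence = tuple[Sequence[str], Sequence[Optional[str]]]


def train_tagger(
    model: AveragedPerceptron,
    sequences: Sequence[TaggedSequence],
    epochs: int,
    seed: int,
) -> None:
    """Greedy-decoding perceptron training; ``None`` tags are unsupervised.

    Mutates ``model`` in place and finalises the averaged weights.  With a
    fixed seed, model state and sequence order, training is deterministic.
    """
    rng = random.Random(seed)
    order = list(range(len(sequences)))
    for _ in range(epochs):
        rng.shuffle(order)
        for idx in order:
            words, tags = sequences[idx]
            prev_tag, prev2_tag = "<s>", "<s>"
            for i, truth in enumerate(tags):
                features = token_features(words, i, prev_tag, prev2_tag)
                guess = model.predict(features, averaged=False)
                if truth is not None:
                    model.update(truth, guess, features)
                    decoded = truth  # teacher forcing keeps context clean
                else:
                    decoded = guess
                prev2_tag, prev_tag = prev_tag, decoded
    model.finalize()


def tag_sequence(model: AveragedPerceptron, words: Sequence[str]) -> list[str]:
    tags: list[str] = []
    prev_tag, prev2_tag = "<s>", "<s>"
    for i in range(len(words)):
        features = token_features(words, i, prev_tag, prev2_tag)
        guess = model.predict(features, averaged=True)
        tags.append(guess)
        prev2_tag, prev_tag = prev_tag, guess
    return tags
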