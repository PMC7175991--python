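"""Tokenisation and sentence splitting with character offsets.

Rule-based and deliberately simple: clinical notes are short, mostly
well-punctuated prose, and every downstream consumer (BIO encoding, negation
scope, experiencer attribution) needs token and sentence boundaries that map
exactly back to character offsets in the original text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

# word = letters/digits possibly joined by internal hyphen/apostrophe
# ("self-harm", "XX's"); everything else is skipped.
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:['’-][A-Za-z0-9]+)*")

# sentence ends at terminal punctuation followed by space, or at a newline
_SENT_BOUNDARY_RE = re.compile(r"[.!?]+[\s]|\n")


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int

    @property
    def lower(self) -> str:
        return self.text.lower()


def tokenize(text: str) -> list[Token]:
    """Split text into word tokens carrying their character offsets."""
    return [Token(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def word_tokens(text: str) -> list[str]:
    """Lower-cased word list without offsets (keyword-matching view)."""
    return [t.lower for t in tokenize(text)]


def sentence_spans(text: str) -> list[tuple[int, int]]:
    """Half-open character ranges of sentences.

    Boundaries are terminal punctuation (. ! ?) followed by whitespace, and
    hard newlines.  Negation and experiencer scope never cross these.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BOUNDARY_RE.finditer(text):
        end = m.end()
        if text[start:end].strip():
            spans.append((start, end))
        start = end
    if text[start:].strip():
        spans.append((start, len(text)))
    return spans


def sentence_containing(text: str, start: int, end: int) -> tuple[int, int]:
    """The sentence range containing offset ``start`` (first overlapping one)."""
    for s, e in sentence_spans(text):
        if s <= start < e:
            return (s, e)
    return (0, len(text))


def tokens_in(tokens: list[Token], start: int, end: int) -> list[int]:
    """Indices of tokens overlapping the character range [start, end)."""
    return [i for i, t in enumerate(tokens) if t.start < end and t.end > start]
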