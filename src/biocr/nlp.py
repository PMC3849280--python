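"""Sentence splitting, biomedical tokenization and the linguistic-layer
provider contract.

Linguistic analysis is organised as an ordered lattice of parsing levels
(tokenization < POS < lemmatization < chunking < dependency parsing).  A
pipeline only ever requests the deepest level some component actually needs,
so a dictionary-only run stops at tokenization.  Real taggers and parsers
attach through the :class:`LinguisticProvider` contract; the built-in default
is a deterministic passthrough stub.
"""

from __future__ import annotations

import enum
import re
from typing import FrozenSet, List, Tuple

from .core import Sentence, Token


class ParsingLevel(enum.IntEnum):
    """Ordered linguistic analysis depth."""

    TOKENIZATION = 0
    POS = 1
    LEMMATIZATION = 2
    CHUNKING = 3
    DEPENDENCY = 4


class CapabilityError(RuntimeError):
    """A provider was asked for a parsing level beyond its capability."""


#: Sentence-terminal periods after these (lower-cased) tokens do not split.
DEFAULT_ABBREVIATIONS: FrozenSet[str] = frozenset(
    {"e.g", "i.e", "al", "fig", "figs", "ref", "refs", "dr", "vs", "etc", "no", "ca", "approx"}
)

_WORD_BEFORE_DOT = re.compile(r"([A-Za-z][A-Za-z.]*)\.$")


def split_sentences(
    text: str, abbreviations: FrozenSet[str] = DEFAULT_ABBREVIATIONS
) -> List[Tuple[int, int]]:
    """Split text into ordered, non-overlapping sentence spans.

    Rule-based default: a run of ``.``, ``?`` or ``!`` ends a sentence when it
    is followed by whitespace and the next non-space character is uppercase or
    a digit, unless the token before a period is a known abbreviation.  Spans
    are trimmed to their non-whitespace extent, so together they cover every
    non-whitespace character of the input.
    """
    if not text.strip():
        return []
    breaks: List[int] = []
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c in ".?!":
            j = i
            while j + 1 < n and text[j + 1] in ".?!":
                j += 1
            k = j + 1
            if k < n and text[k].isspace():
                m = k
                while m < n and text[m].isspace():
                    m += 1
                if m < n and (text[m].isupper() or text[m].isdigit()):
                    abbrev = False
                    if c == ".":
                        w = _WORD_BEFORE_DOT.search(text[: i + 1])
                        if w and w.group(1).lower() in abbreviations:
                            abbrev = True
                    if not abbrev:
                        breaks.append(j + 1)
            i = j + 1
        else:
            i += 1
    spans: List[Tuple[int, int]] = []
    prev = 0
    for b in breaks + [n]:
        seg = text[prev:b]
        lead = len(seg) - len(seg.lstrip())
        trail = len(seg) - len(seg.rstrip())
        if seg.strip():
            spans.append((prev + lead, b - trail))
        prev = b
    return spans


_TOKEN = re.compile(r"\w+|\S", re.UNICODE)


def tokenize(sentence_text: str) -> List[Token]:
    """Tokenize biomedical text.

    Whitespace delimits words; within a word, runs of alphanumerics stay
    together and every other symbol — in particular ``/``, ``-`` and ``.`` —
    becomes a token of its own, so "N-acetyl-cysteine" yields five tokens.
    Letter-digit boundaries ("IL2") are never split.  Token extents tile the
    non-whitespace characters, so the sentence can be reconstructed from
    surfaces plus the original gaps.
    """
    tokens: List[Token] = []
    for word in re.finditer(r"\S+", sentence_text):
        for m in _TOKEN.finditer(word.group(0)):
            start = word.start() + m.start()
            end = word.start() + m.end()
            tokens.append(
                Token(index=len(tokens), start=start, end=end, surface=m.group(0))
            )
    return tokens


class LinguisticProvider:
    """Contract for components that fill lemma / POS / chunk token fields.

    ``capability`` is the deepest :class:`ParsingLevel` the provider can
    serve; :meth:`annotate` must fill every requested level up to that bound
    and leave deeper fields untouched.
    """

    name = "provider"
    capability: ParsingLevel = ParsingLevel.TOKENIZATION
    #: whether one instance may be shared across concurrent workers
    shareable: bool = True

    def annotate(self, sentence: Sentence, level: ParsingLevel) -> None:
        raise NotImplementedError


class PassthroughProvider(LinguisticProvider):
    """Deterministic stub provider: lowercased surface as lemma, a fixed POS
    tag and an O chunk.  It exists so that pipelines and machine-learning
    providers that require these layers can run without an external parser."""

    name = "passthrough"

    def __init__(self, capability: ParsingLevel = ParsingLevel.CHUNKING,
                 pos_tag: str = "NN"):
        self.capability = capability
        self.pos_tag = pos_tag

    def annotate(self, sentence: Sentence, level: ParsingLevel) -> None:
        for t in sentence.tokens:
            if level >= ParsingLevel.POS:
                t.pos = self.pos_tag
            if level >= ParsingLevel.LEMMATIZATION:
                t.lemma = t.surface.lower()
            if level >= ParsingLevel.CHUNKING:
                t.chunk = "O"


def annotate_layers(
    sentence: Sentence, provider: LinguisticProvider, level: ParsingLevel
) -> Sentence:
    """Fill linguistic layers up to ``level`` using ``provider``.

    All token fields for levels <= ``level`` become non-null; deeper fields
    are left untouched (lazy resolution: a model needing lemmas never pays
    for chunking).
    """
    if level > provider.capability:
        raise CapabilityError(
            f"provider {provider.name!r} caps at {provider.capability.name}, "
            f"{level.name} requested"
        )
    if level > ParsingLevel.TOKENIZATION:
        provider.annotate(sentence, level)
    if level > sentence.parsed_level:
        sentence.parsed_level = level
    return sentence
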