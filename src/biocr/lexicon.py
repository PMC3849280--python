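"""Concept dictionaries: loading, automaton compilation and sentence matching.

A dictionary is a TSV file with two fields per line — an identifier quadruple
and a pipe-joined list of names.  Dictionaries live in a folder next to a
priority file that lists their file names one per line; the line order fixes
both the matching priority and the normalization order.

Matching is case-insensitive exact: approximate matching over large
biomedical lexicons floods the output with false positives, whereas
orthographic variants can simply be added to the dictionary as extra names.
Two filters guard against degenerate surfaces: a configurable stopword list
of non-informative words, and a minimum surface length (names of two
characters or fewer are discarded — short acronyms are recovered later by
abbreviation resolution instead).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .automaton import Automaton
from .core import Annotation, Identifier, MalformedIdentifierError, Provenance, Sentence, parse_identifier

logger = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 3


class DictionaryLoadError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


def fold(s: str) -> str:
    """Case-folding used throughout matching: simple lowercase."""
    return s.lower()


@dataclass
class Dictionary:
    """One compiled dictionary: case-folded surface -> ordered identifiers."""

    name: str
    entries: Dict[str, List[Identifier]] = field(default_factory=dict)
    priority_rank: int = 0

    def add(self, surface: str, identifier: Identifier) -> None:
        key = fold(surface)
        ids = self.entries.setdefault(key, [])
        if identifier not in ids:
            ids.append(identifier)

    def __len__(self) -> int:
        return len(self.entries)


def load_dictionary(path: str, priority_rank: int = 0) -> Dictionary:
    """Load one TSV dictionary (``identifier<TAB>name1|name2|...`` per line).

    Identical (surface, identifier) pairs are de-duplicated; identical
    surfaces on different lines accumulate identifiers.  Blank lines are
    skipped; a missing TAB or a malformed identifier raises
    :class:`DictionaryLoadError` with the line number.
    """
    name = os.path.splitext(os.path.basename(path))[0]
    d = Dictionary(name=name, priority_rank=priority_rank)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DictionaryLoadError(f"{path}:{lineno}: expected identifier<TAB>names")
            try:
                identifier = parse_identifier(parts[0])
            except MalformedIdentifierError as exc:
                raise DictionaryLoadError(f"{path}:{lineno}: {exc}") from exc
            for surface in parts[1].split("|"):
                if surface:
                    d.add(surface, identifier)
    return d


@dataclass
class DictionaryGroup:
    """Ordered dictionaries (order = priority) plus the matching filters."""

    dictionaries: List[Dictionary] = field(default_factory=list)
    stopwords: FrozenSet[str] = frozenset()
    min_length: int = DEFAULT_MIN_LENGTH

    def __iter__(self):
        return iter(self.dictionaries)

    def __len__(self) -> int:
        return len(self.dictionaries)


DEFAULT_PRIORITY_FILENAME = "priority"


def load_group(
    folder: str,
    priority_file: Optional[str] = None,
    stopwords: FrozenSet[str] = frozenset(),
    min_length: int = DEFAULT_MIN_LENGTH,
) -> DictionaryGroup:
    """Load every dictionary listed in the priority file, in that order.

    The priority file defaults to ``<folder>/priority``; ``#`` starts a
    comment line.  A listed file missing from the folder is a configuration
    error; files present in the folder but not listed are ignored with a
    warning.
    """
    if priority_file is None:
        priority_file = os.path.join(folder, DEFAULT_PRIORITY_FILENAME)
    if not os.path.isfile(priority_file):
        raise ConfigurationError(f"priority file not found: {priority_file}")
    listed: List[str] = []
    with open(priority_file, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                listed.append(line)
    dictionaries: List[Dictionary] = []
    for rank, fname in enumerate(listed):
        path = os.path.join(folder, fname)
        if not os.path.isfile(path):
            raise ConfigurationError(f"dictionary listed in priority file is missing: {fname}")
        dictionaries.append(load_dictionary(path, priority_rank=rank))
    unlisted = [
        f
        for f in sorted(os.listdir(folder))
        if f.endswith(".tsv") and f not in listed
    ]
    for f in unlisted:
        logger.warning("dictionary file %s not listed in priority file; ignored", f)
    return DictionaryGroup(dictionaries=dictionaries, stopwords=stopwords, min_length=min_length)


class Matcher:
    """Per-dictionary compiled automata over case-folded text."""

    shareable = True  # read-only after construction

    def __init__(self, group: DictionaryGroup):
        self.group = group
        self.automata: List[Automaton] = [
            Automaton(d.entries.keys()) for d in group.dictionaries
        ]

    def candidates(self, folded_text: str) -> List[List[Tuple[int, int]]]:
        """Raw occurrences of each dictionary's surfaces, per dictionary."""
        out: List[List[Tuple[int, int]]] = []
        for automaton in self.automata:
            spans = sorted({(s, e) for s, e, _ in automaton.iter_matches(folded_text)})
            out.append(spans)
        return out


def _fold_preserving_length(text: str) -> str:
    # str.lower can change length for a handful of Unicode characters;
    # offsets must survive folding, so fold per character.
    folded = text.lower()
    if len(folded) == len(text):
        return folded
    return "".join(c.lower()[0] if len(c.lower()) == 1 else c for c in text)


def match_sentence(
    sentence: Sentence,
    group: DictionaryGroup,
    matcher: Optional[Matcher] = None,
) -> List[Annotation]:
    """Run dictionary matching over one tokenized sentence.

    Pipeline of directives, applied per dictionary then pooled:

    1. candidate matches are case-insensitive exact occurrences of dictionary
       surfaces whose extents start at a token start and end at a token end;
    2. within one dictionary only the entry with the largest span survives:
       candidates contained in another candidate of the same dictionary are
       dropped, and remaining same-dictionary partial overlaps are resolved
       leftmost-longest;
    3. candidates whose folded surface is a stopword are dropped;
    4. candidates shorter than ``group.min_length`` characters are dropped;
    5. survivors from all dictionaries are inserted into the sentence tree,
       equal spans merging their identifier lists in dictionary-priority
       order.

    Returns the annotations inserted (one per distinct surviving span).
    """
    if not sentence.tokens:
        raise ValueError("sentence must be tokenized before dictionary matching")
    if matcher is None:
        matcher = Matcher(group)
    folded = _fold_preserving_length(sentence.text)
    token_starts = {t.start for t in sentence.tokens}
    token_ends = {t.end for t in sentence.tokens}

    span_ids: Dict[Tuple[int, int], List[Identifier]] = {}
    for d, all_spans in zip(group.dictionaries, matcher.candidates(folded)):
        spans = [
            (s, e) for s, e in all_spans if s in token_starts and e in token_ends
        ]
        spans = _drop_contained(spans)
        spans = _leftmost_longest(spans)
        for s, e in spans:
            surface = folded[s:e]
            if surface in group.stopwords:
                continue
            if e - s < group.min_length:
                continue
            ids = span_ids.setdefault((s, e), [])
            for i in d.entries[surface]:
                if i not in ids:
                    ids.append(i)

    annotations: List[Annotation] = []
    for (s, e) in sorted(span_ids, key=lambda se: (se[0], -se[1])):
        ann = Annotation(
            start=s,
            end=e,
            ids=span_ids[(s, e)],
            provenance=Provenance.DICTIONARY,
            token_span=sentence.token_span_for(s, e),
        )
        annotations.append(sentence.tree.insert(ann))
    return annotations


def _drop_contained(spans: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Drop spans properly contained in another span of the same dictionary."""
    out = []
    for s, e in spans:
        contained = any(
            (s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in spans
        )
        if not contained:
            out.append((s, e))
    return out


def _leftmost_longest(spans: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Resolve partial overlaps greedily: leftmost start, then longest."""
    kept: List[Tuple[int, int]] = []
    for s, e in sorted(spans, key=lambda se: (se[0], -(se[1] - se[0]))):
        if all(e2 <= s or e <= s2 for s2, e2 in kept):
            kept.append((s, e))
    return sorted(kept)
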