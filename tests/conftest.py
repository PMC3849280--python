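"""Shared helpers: sentence construction, identifier shorthand, and an
independent brute-force dictionary-matching oracle used to cross-check the
automaton matcher."""

from __future__ import annotations

import random
from typing import Dict, List, Set, Tuple

import pytest

from biocr.core import Annotation, Identifier, Sentence
from biocr.lexicon import Dictionary, DictionaryGroup
from biocr.nlp import tokenize


def ident(source="SRC", id="1", type="t", group="PRGE") -> Identifier:
    return Identifier(source, id, type, group)


def make_sentence(text: str, sid: int = 0, start: int = 0) -> Sentence:
    return Sentence(sid=sid, start=start, end=start + len(text), text=text,
                    tokens=tokenize(text))


def make_dictionary(name: str, entries: Dict[str, List[Identifier]],
                    rank: int = 0) -> Dictionary:
    d = Dictionary(name=name, priority_rank=rank)
    for surface, ids in entries.items():
        for i in ids:
            d.add(surface, i)
    return d


def brute_force_match(
    sentence: Sentence, group: DictionaryGroup
) -> Dict[Tuple[int, int], List[Identifier]]:
    """O(n^2) reference matcher: look up every token-aligned substring in
    every dictionary and apply the same directives as the production matcher
    (largest span within a dictionary, leftmost-longest on partial overlaps,
    stopword and minimum-length filters).  Shares no code with the automaton
    path."""
    folded = sentence.text.lower()
    starts = sorted({t.start for t in sentence.tokens})
    ends = sorted({t.end for t in sentence.tokens})
    result: Dict[Tuple[int, int], List[Identifier]] = {}
    for d in group.dictionaries:
        spans = []
        for s in starts:
            for e in ends:
                if e > s and folded[s:e] in d.entries:
                    spans.append((s, e))
        # largest span within one dictionary
        spans = [
            (s, e)
            for (s, e) in spans
            if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for (s2, e2) in spans)
        ]
        # leftmost-longest among remaining partial overlaps
        kept: List[Tuple[int, int]] = []
        for s, e in sorted(spans, key=lambda se: (se[0], se[0] - se[1])):
            if all(e2 <= s or e <= s2 for (s2, e2) in kept):
                kept.append((s, e))
        for s, e in kept:
            surface = folded[s:e]
            if surface in group.stopwords or e - s < group.min_length:
                continue
            ids = result.setdefault((s, e), [])
            for i in d.entries[surface]:
                if i not in ids:
                    ids.append(i)
    return result


def random_match_fixture(rng: random.Random):
    """One random (sentence, dictionary group) pair for oracle comparison.

    Sentences mix dictionary surfaces, near-miss words and punctuation so
    that token-boundary handling, nesting and overlap resolution are all
    exercised."""
    alphabet = ["rat", "rats", "cell", "factor", "breast", "cancer", "acid",
                "il", "p53", "kinase", "gene", "tumor", "alpha", "beta",
                "strata", "ratio", "cellular", "factors"]
    n_dicts = rng.randint(1, 3)
    dicts = []
    for k in range(n_dicts):
        d = Dictionary(name=f"d{k}", priority_rank=k)
        for _ in range(rng.randint(2, 8)):
            n_words = rng.randint(1, 3)
            surface = " ".join(rng.choice(alphabet) for _ in range(n_words))
            d.add(surface, Identifier("FX", f"{k}-{rng.randint(0, 99)}", "t",
                                      rng.choice(["PRGE", "DISO", "SPEC"])))
        dicts.append(d)
    stopwords = frozenset(rng.sample(alphabet, rng.randint(0, 2)))
    group = DictionaryGroup(dictionaries=dicts, stopwords=stopwords,
                            min_length=rng.choice([1, 3, 4]))
    words = [rng.choice(alphabet + ["-", ".", "the", "was", "in"])
             for _ in range(rng.randint(3, 14))]
    sentence = make_sentence(" ".join(words))
    return sentence, group


def tree_shape(tree) -> List[Tuple[Tuple[int, int], int, Tuple[str, ...]]]:
    """Canonical serialization of a tree: (span, depth, sorted id strings)."""
    return [
        (a.span, tree.depth_of(a), tuple(sorted(str(i) for i in a.ids)))
        for a in tree.traverse()
    ]
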