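"""Seeded generators of synthetic dictionaries and gold-annotated documents.

Every stage of the pipeline is testable without external corpora: the
generator builds pronounceable concept names, distributes them over
prioritized dictionaries with controlled ambiguity, nesting and abbreviation
definitions, and plants them into carrier sentences at known offsets.  The
carrier vocabulary is disjoint from every generated name and each concept
uses fresh words (except for deliberately nested pairs), so the planted
annotations are provably the complete set of dictionary matches — the gold
standard is exact by construction, not by approximation.

Identical :class:`FixtureSpec` values produce bit-identical fixtures.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core import Identifier
from .evaluation import EvalUnit
from .lexicon import Dictionary, DictionaryGroup

#: carrier words never used as concept names; sentence starters are capitalized
_STARTERS = ["Results", "Analysis", "Observation", "Measurements", "Findings", "Samples"]
_CARRIERS = [
    "indicate", "that", "observed", "profile", "remained", "during", "under",
    "standard", "conditions", "with", "increased", "levels", "compared", "control",
    "groups", "showed", "consistent", "signal", "across", "replicates",
]
_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"
_GROUPS = ["PRGE", "DISO", "SPEC", "ANAT", "CHED"]
_DICT_NAMES = ["alpha.tsv", "beta.tsv", "gamma.tsv"]

_FORBIDDEN = {w.lower() for w in _STARTERS} | set(_CARRIERS)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic fixture set."""

    seed: int = 0
    n_concepts: int = 40
    n_docs: int = 8
    sentences_per_doc: int = 6
    ambiguity_rate: float = 0.2
    nesting_rate: float = 0.25
    abbreviation_rate: float = 0.25


@dataclass
class GoldDocument:
    doc_id: str
    text: str
    gold: List[EvalUnit] = field(default_factory=list)


@dataclass
class FixtureSet:
    """Everything one seed generates: the dictionary group, the ground-truth
    surface map and the abbreviation inventory."""

    group: DictionaryGroup
    #: surface -> identifiers exactly as dictionary matching would merge them
    truth: Dict[str, List[Identifier]]
    #: (long form surface, short form) definition pairs available for planting
    abbreviations: List[Tuple[str, str]]
    #: (outer surface, inner surface, char offset of inner within outer)
    nested_pairs: List[Tuple[str, str, int]]

    def dictionary_tsv(self) -> Dict[str, str]:
        """Render each dictionary back to its TSV file content."""
        files: Dict[str, str] = {}
        for d in self.group.dictionaries:
            by_id: Dict[Identifier, List[str]] = {}
            for surface, ids in sorted(d.entries.items()):
                for i in ids:
                    by_id.setdefault(i, []).append(surface)
            lines = [f"{i}\t{'|'.join(names)}" for i, names in by_id.items()]
            files[f"{d.name}.tsv"] = "\n".join(lines) + ("\n" if lines else "")
        return files


def _make_word(rng: random.Random, used: set, min_syllables: int = 2) -> str:
    while True:
        n = rng.randint(min_syllables, 3)
        word = "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n))
        if word not in used and word not in _FORBIDDEN and len(word) >= 3:
            used.add(word)
            return word


def gen_dictionary_group(
    spec: FixtureSpec,
) -> Tuple[DictionaryGroup, Dict[str, List[Identifier]]]:
    """Generate the prioritized dictionary group and its ground-truth map."""
    fx = build_fixture_set(spec)
    return fx.group, fx.truth


def build_fixture_set(spec: FixtureSpec) -> FixtureSet:
    if spec.n_concepts <= 0 or spec.n_docs <= 0 or spec.sentences_per_doc <= 0:
        raise ValueError("fixture counts must be positive")
    rng = random.Random(spec.seed)
    used_words: set = set()
    dictionaries = [
        Dictionary(name=os.path.splitext(n)[0], priority_rank=i)
        for i, n in enumerate(_DICT_NAMES)
    ]
    truth: Dict[str, List[Identifier]] = {}
    abbreviations: List[Tuple[str, str]] = []
    nested_pairs: List[Tuple[str, str, int]] = []
    singles: List[Tuple[int, str]] = []  # (dict index, single-word surface)
    next_id = 0

    def new_id(group: str) -> Identifier:
        nonlocal next_id
        next_id += 1
        return Identifier("FX", f"{next_id:04d}", "concept", group)

    def register(surface: str, dict_idx: int, ids: Sequence[Identifier]) -> None:
        for i in ids:
            dictionaries[dict_idx].add(surface, i)
        merged = truth.setdefault(surface, [])
        for i in ids:
            if i not in merged:
                merged.append(i)

    for k in range(spec.n_concepts):
        dict_idx = rng.randrange(len(dictionaries))
        group_label = rng.choice(_GROUPS)
        roll = rng.random()
        if roll < spec.nesting_rate and singles:
            # outer concept embedding an existing single-word surface from
            # another dictionary: nested matches are suppressed within one
            # dictionary (largest span wins) but not across dictionaries
            inner_dict, inner = rng.choice(singles)
            outer_dict = rng.choice([i for i in range(len(dictionaries)) if i != inner_dict])
            extra = _make_word(rng, used_words)
            if rng.random() < 0.5:
                surface = f"{extra} {inner}"
                offset = len(extra) + 1
            else:
                surface = f"{inner} {extra}"
                offset = 0
            ids = [new_id(group_label)]
            if rng.random() < spec.ambiguity_rate:
                ids.append(new_id(rng.choice(_GROUPS)))
            register(surface, outer_dict, ids)
            nested_pairs.append((surface, inner, offset))
            continue
        if roll < spec.nesting_rate + spec.abbreviation_rate:
            # long-form concept with a derivable short form (initials);
            # distinct initials guarantee the definition extractor recovers
            # exactly the full three-word form as the long form
            words = [_make_word(rng, used_words)]
            while len(words) < 3:
                w = _make_word(rng, used_words)
                if w[0] not in {x[0] for x in words}:
                    words.append(w)
            surface = " ".join(words)
            sf = "".join(w[0] for w in words).upper()
            ids = [new_id(group_label)]
            register(surface, dict_idx, ids)
            abbreviations.append((surface, sf))
            continue
        n_words = 2 if rng.random() < 0.3 else 1
        surface = " ".join(_make_word(rng, used_words) for _ in range(n_words))
        ids = [new_id(group_label)]
        if rng.random() < spec.ambiguity_rate:
            ids.append(new_id(rng.choice(_GROUPS)))
        register(surface, dict_idx, ids)
        duplicated = rng.random() < 0.1
        if duplicated:
            # cross-dictionary duplication: same surface, different identifier
            other = rng.choice([i for i in range(len(dictionaries)) if i != dict_idx])
            register(surface, other, [new_id(group_label)])
        if n_words == 1 and not duplicated:
            # nesting candidates must live in exactly one dictionary, or the
            # same-dictionary largest-span rule would hide part of their ids
            singles.append((dict_idx, surface))

    group = DictionaryGroup(dictionaries=dictionaries, stopwords=frozenset(), min_length=3)
    return FixtureSet(group=group, truth=truth, abbreviations=abbreviations,
                      nested_pairs=nested_pairs)


def gen_gold_corpus(
    spec: FixtureSpec, fixture_set: Optional[FixtureSet] = None
) -> List[GoldDocument]:
    """Generate documents with planted mentions and their exact gold.

    Sentences are carrier templates with dictionary surfaces planted at
    known offsets; nested surfaces contribute gold for both levels; planted
    abbreviation definitions contribute gold for the defining short form and
    every later short-form occurrence.  Offsets are document-absolute.
    """
    if fixture_set is None:
        fixture_set = build_fixture_set(spec)
    rng = random.Random(spec.seed + 1)
    inner_by_outer = {o: (i, off) for o, i, off in fixture_set.nested_pairs}
    plain_surfaces = [
        s for s in fixture_set.truth
        if s not in {lf for lf, _ in fixture_set.abbreviations}
    ]
    docs: List[GoldDocument] = []
    for d in range(spec.n_docs):
        parts: List[str] = []
        gold: List[EvalUnit] = []
        pos = 0
        pending_sf: List[Tuple[str, List[Identifier]]] = []

        def emit(fragment: str) -> None:
            nonlocal pos
            parts.append(fragment)
            pos += len(fragment)

        def plant(surface: str, ids: List[Identifier]) -> None:
            start = pos
            emit(surface)
            group_label = ids[0].group if ids else "UNKN"
            gold.append(EvalUnit(start=start, end=start + len(surface),
                                 group=group_label, ids=list(ids)))
            inner = inner_by_outer.get(surface)
            if inner is not None:
                inner_surface, off = inner
                gold.append(
                    EvalUnit(
                        start=start + off,
                        end=start + off + len(inner_surface),
                        group=fixture_set.truth[inner_surface][0].group,
                        ids=list(fixture_set.truth[inner_surface]),
                    )
                )

        for s in range(spec.sentences_per_doc):
            if s > 0:
                emit(" ")
            emit(rng.choice(_STARTERS) + " ")
            emit(" ".join(rng.sample(_CARRIERS, 3)) + " ")
            action = rng.random()
            if action < 0.25 and fixture_set.abbreviations:
                lf, sf = rng.choice(fixture_set.abbreviations)
                ids = fixture_set.truth[lf]
                plant(lf, ids)
                emit(" (")
                sf_start = pos
                emit(sf)
                gold.append(EvalUnit(start=sf_start, end=sf_start + len(sf),
                                     group=ids[0].group, ids=list(ids)))
                emit(")")
                pending_sf.append((sf, list(ids)))
            elif action < 0.45 and pending_sf:
                sf, ids = rng.choice(pending_sf)
                sf_start = pos
                emit(sf)
                gold.append(EvalUnit(start=sf_start, end=sf_start + len(sf),
                                     group=ids[0].group, ids=list(ids)))
            else:
                surface = rng.choice(plain_surfaces)
                plant(surface, fixture_set.truth[surface])
            emit(" " + " ".join(rng.sample(_CARRIERS, 2)) + ".")
        docs.append(GoldDocument(doc_id=f"doc{d:03d}", text="".join(parts), gold=gold))
    return docs


def write_fixture_files(spec: FixtureSpec, out_dir: str) -> None:
    """Materialize a fixture set on disk: ``dictionaries/`` with its priority
    file, ``docs/`` with raw text and ``gold/`` with A1 standoff."""
    fx = build_fixture_set(spec)
    dict_dir = os.path.join(out_dir, "dictionaries")
    docs_dir = os.path.join(out_dir, "docs")
    gold_dir = os.path.join(out_dir, "gold")
    for p in (dict_dir, docs_dir, gold_dir):
        os.makedirs(p, exist_ok=True)
    for fname, content in fx.dictionary_tsv().items():
        with open(os.path.join(dict_dir, fname), "w", encoding="utf-8") as fh:
            fh.write(content)
    with open(os.path.join(dict_dir, "priority"), "w", encoding="utf-8") as fh:
        for d in fx.group.dictionaries:
            fh.write(f"{d.name}.tsv\n")
    for doc in gen_gold_corpus(spec, fx):
        with open(os.path.join(docs_dir, f"{doc.doc_id}.txt"), "w", encoding="utf-8") as fh:
            fh.write(doc.text)
        with open(os.path.join(gold_dir, f"{doc.doc_id}.a1"), "w", encoding="utf-8") as fh:
            for n, u in enumerate(doc.gold, start=1):
                fh.write(f"T{n}\t{u.group} {u.start} {u.end}\t{doc.text[u.start:u.end]}\n")
            for n, u in enumerate(doc.gold, start=1):
                if u.ids:
                    joined = "|".join(str(i) for i in u.ids)
                    fh.write(f"#{n}\tAnnotatorNotes T{n}\t{joined}\n")
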