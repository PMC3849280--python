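"""Machine-learning NER provider contract and prioritized-dictionary
normalization.

Statistical named-entity recognizers (CRF taggers and the like) find mention
boundaries but produce no database identifiers.  Providers plug in through
:class:`NerProvider`; the normalization step then resolves each mention
against an ordered list of dictionaries: the first dictionary that yields a
match wins and the search stops.  With preferred names in the first
dictionary and synonym lists behind it, an ambiguous symbol resolves to the
preferred reading (e.g. "TRAF2" to the TRAF2 protein rather than to the TANK
synonym listed at lower priority).

A match may be partial — a dictionary surface covering only a sub-span of
the mention is accepted as an identifier for the whole mention ("BRCA1"
covering "BRCA1 gene") — but extra tokens are tolerated only on the mention
side, never on the dictionary side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core import Annotation, Identifier, Provenance, Sentence, Token
from .lexicon import DictionaryGroup, fold
from .nlp import CapabilityError, ParsingLevel


class ContractViolationError(RuntimeError):
    """A provider returned a mention outside its sentence or off token
    boundaries."""


class NerProvider:
    """Contract for pluggable mention recognizers.

    ``required_level`` declares the linguistic features the model needs;
    :meth:`predict` maps a sentence to ``(first_token, last_token, group)``
    token-index triples.  Identifiers are attached later by normalization.
    """

    name = "ner"
    required_level: ParsingLevel = ParsingLevel.TOKENIZATION
    #: whether one instance may be shared across concurrent workers
    shareable: bool = False

    def predict(self, sentence: Sentence) -> List[Tuple[int, int, str]]:
        raise NotImplementedError


class GazetteerNerProvider(NerProvider):
    """Reference provider backed by a surface gazetteer.

    Scans token n-grams (longest first, left to right, non-overlapping) for
    case-folded gazetteer entries.  It satisfies the provider contract with
    fully deterministic behaviour, which makes it the workhorse of the test
    suite and a reasonable baseline recognizer.
    """

    shareable = True

    def __init__(self, gazetteer: Dict[str, str], name: str = "gazetteer",
                 required_level: ParsingLevel = ParsingLevel.TOKENIZATION,
                 max_tokens: int = 8):
        #: folded surface -> semantic group
        self.gazetteer = {fold(k): v for k, v in gazetteer.items()}
        self.name = name
        self.required_level = required_level
        self.max_tokens = max_tokens

    def predict(self, sentence: Sentence) -> List[Tuple[int, int, str]]:
        tokens = sentence.tokens
        taken = [False] * len(tokens)
        mentions: List[Tuple[int, int, str]] = []
        for width in range(min(self.max_tokens, len(tokens)), 0, -1):
            for i in range(0, len(tokens) - width + 1):
                j = i + width - 1
                if any(taken[i: j + 1]):
                    continue
                text = sentence.text[tokens[i].start: tokens[j].end]
                group = self.gazetteer.get(fold(text))
                if group is not None:
                    mentions.append((i, j, group))
                    for k in range(i, j + 1):
                        taken[k] = True
        return sorted(mentions)


def recognize(sentence: Sentence, provider: NerProvider) -> List[Annotation]:
    """Run one NER provider over a sentence.

    Returns one annotation per predicted mention with empty identifier list
    (provenance ML); normalization attaches identifiers afterwards.  The
    sentence must already be parsed to the provider's required level.
    """
    if sentence.parsed_level < provider.required_level:
        raise CapabilityError(
            f"provider {provider.name!r} needs {provider.required_level.name}, "
            f"sentence parsed to {sentence.parsed_level.name}"
        )
    annotations: List[Annotation] = []
    n = len(sentence.tokens)
    for first, last, group in provider.predict(sentence):
        if not (0 <= first <= last < n):
            raise ContractViolationError(
                f"provider {provider.name!r} returned token span ({first},{last}) "
                f"outside sentence of {n} tokens"
            )
        ann = Annotation(
            start=sentence.tokens[first].start,
            end=sentence.tokens[last].end,
            ids=[],
            provenance=Provenance.ML,
            token_span=(first, last),
        )
        ann.predicted_group = group  # type: ignore[attr-defined]
        annotations.append(ann)
    return annotations


def load_provider_registry(folder: str):
    """Read the model registry: one ``*.properties`` file per provider.

    Keys (``key=value`` lines, ``#`` comments): ``name``, ``required_level``
    (a :class:`ParsingLevel` name), ``type`` (only ``gazetteer`` is built
    in), ``gazetteer`` (path, relative to the properties file, of a
    ``surface<TAB>group`` TSV).  Returns name -> zero-argument factory so a
    context can instantiate providers lazily.
    """
    import os

    registry = {}
    for fname in sorted(os.listdir(folder)):
        if not fname.endswith(".properties"):
            continue
        path = os.path.join(folder, fname)
        props = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#") and "=" in line:
                    k, v = line.split("=", 1)
                    props[k.strip()] = v.strip()
        name = props.get("name", os.path.splitext(fname)[0])
        level = ParsingLevel[props.get("required_level", "TOKENIZATION").upper()]
        kind = props.get("type", "gazetteer")
        if kind != "gazetteer":
            raise ValueError(f"{path}: unknown provider type {kind!r}")
        gaz_path = os.path.join(os.path.dirname(path), props.get("gazetteer", ""))

        def factory(name=name, level=level, gaz_path=gaz_path):
            gazetteer = {}
            with open(gaz_path, encoding="utf-8") as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if line:
                        surface, group = line.split("\t")
                        gazetteer[surface] = group
            return GazetteerNerProvider(gazetteer, name=name, required_level=level)

        registry[name] = factory
    return registry


@dataclass
class NormalizationPolicy:
    """Dictionaries used for normalization plus the keep-or-discard switch
    for mentions that no dictionary resolves."""

    group: DictionaryGroup
    keep_unmatched: bool = False


def normalize_mention(
    mention_text: str,
    mention_tokens: Sequence[Token],
    policy: NormalizationPolicy,
) -> List[Identifier]:
    """Resolve a mention against prioritized dictionaries.

    For each dictionary in priority order, find the longest token-aligned
    sub-span of the mention whose case-folded text is a surface of that
    dictionary (the full mention is the longest candidate; ties on character
    length break leftmost).  The first dictionary with a match supplies all
    identifiers of the winning surface and the search stops.  Returns an
    empty list when no dictionary matches.
    """
    if not mention_tokens:
        return []
    base = mention_tokens[0].start
    candidates: List[Tuple[int, int, str]] = []  # (char_len, -start) ordering below
    for i in range(len(mention_tokens)):
        for j in range(i, len(mention_tokens)):
            s = mention_tokens[i].start - base
            e = mention_tokens[j].end - base
            if 0 <= s < e <= len(mention_text):
                candidates.append((s, e, fold(mention_text[s:e])))
    # longest sub-span first, leftmost on ties
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    for dictionary in policy.group.dictionaries:
        for s, e, surface in candidates:
            ids = dictionary.entries.get(surface)
            if ids:
                return list(ids)
    return []


def apply_normalization(
    sentence: Sentence,
    ml_annotations: Sequence[Annotation],
    policy: NormalizationPolicy,
) -> None:
    """Attach identifiers to ML mentions and insert survivors into the tree.

    Mentions that no dictionary resolves are kept (with empty identifier
    list) or discarded according to ``policy.keep_unmatched``.
    """
    for ann in ml_annotations:
        first, last = ann.token_span if ann.token_span else (None, None)
        if first is None:
            span = sentence.token_span_for(ann.start, ann.end)
            if span is None:
                raise ContractViolationError("ML annotation is not token-aligned")
            first, last = span
        tokens = sentence.tokens[first: last + 1]
        ids = normalize_mention(sentence.text[ann.start: ann.end], tokens, policy)
        if ids:
            ann.merge_ids(ids)
            sentence.tree.insert(ann)
        elif policy.keep_unmatched:
            sentence.tree.insert(ann)
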