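"""Post-processing: abbreviation resolution and tree disambiguation.

Abbreviation resolution follows the classic pattern-matching recipe for
definition phrases ("long form (SF)"): a parenthesized short form is paired
with the shortest preceding word suffix whose characters contain the short
form in order.  When one of the two forms already carries identifiers, the
counterpart — and every later occurrence of it in the same document — is
annotated with the same identifiers.  This recovers short acronyms that the
dictionary length filter deliberately refuses to match.

Three structural disambiguation strategies prune the concept tree: by depth,
by removing concepts nested inside a larger concept of the same semantic
group, and by a prioritized list of semantic groups that resolves every
nesting or intersection down to a flat, overlap-free annotation set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .core import Annotation, ConceptTree, Corpus, Provenance, Sentence

# -- abbreviation resolution -------------------------------------------------

#: short-form shape constraints (config-overridable at call sites)
SF_MIN_CHARS = 2
SF_MAX_CHARS = 10
SF_MAX_WORDS = 2

_PARENS = re.compile(r"\(([^()]*)\)")
_WORD = re.compile(r"\S+")


@dataclass
class AbbreviationPair:
    """A (long form, short form) definition found in one sentence; spans are
    sentence-relative."""

    sid: int
    short_span: Tuple[int, int]
    short_text: str
    long_span: Tuple[int, int]
    long_text: str


def _is_subsequence(needle: str, haystack: str) -> bool:
    it = iter(haystack)
    return all(ch in it for ch in needle)


def extract_abbreviations(sentence: Sentence) -> List[AbbreviationPair]:
    """Find abbreviation definitions of the shape "long form (SF)".

    A candidate short form is the parenthesized text when it has at most
    two words, 2-10 characters, at least one letter and an alphanumeric
    first character.  The long-form search window holds up to
    ``min(len(SF) + 5, 2 * len(SF))`` words before the open parenthesis;
    a window suffix is valid when every short-form character occurs in it
    in order (case-insensitive) and the short form's first character starts
    one of its words.  The shortest valid suffix is the long form.
    """
    pairs: List[AbbreviationPair] = []
    text = sentence.text
    for m in _PARENS.finditer(text):
        inner = m.group(1)
        stripped = inner.strip()
        if not stripped:
            continue
        lead = len(inner) - len(inner.lstrip())
        sf_start = m.start(1) + lead
        sf_end = sf_start + len(stripped)
        sf = stripped
        if not (SF_MIN_CHARS <= len(sf) <= SF_MAX_CHARS):
            continue
        if len(sf.split()) > SF_MAX_WORDS:
            continue
        if not any(c.isalpha() for c in sf):
            continue
        if not sf[0].isalnum():
            continue
        words = [w for w in _WORD.finditer(text, 0, m.start()) if w.end() <= m.start()]
        if not words:
            continue
        max_words = min(len(sf) + 5, 2 * len(sf))
        window = words[-max_words:] if max_words else []
        best: Optional[Tuple[int, int]] = None
        for k in range(1, len(window) + 1):
            suffix = window[-k:]
            lf_start, lf_end = suffix[0].start(), suffix[-1].end()
            lf_text = text[lf_start:lf_end]
            if not _is_subsequence(sf.lower(), lf_text.lower()):
                continue
            if not any(w.group(0).lower().startswith(sf[0].lower()) for w in suffix):
                continue
            best = (lf_start, lf_end)
            break
        if best is None:
            continue
        pairs.append(
            AbbreviationPair(
                sid=sentence.sid,
                short_span=(sf_start, sf_end),
                short_text=sf,
                long_span=best,
                long_text=text[best[0]: best[1]],
            )
        )
    return pairs


def extend_by_abbreviations(corpus: Corpus) -> Corpus:
    """Propagate identifiers between abbreviation forms, in place.

    For each definition pair found in the document: when exactly one of the
    two forms coincides with an existing annotation's extent, the counterpart
    span is inserted as a new annotation carrying the same identifiers
    (provenance ABBREVIATION), and every later occurrence of the newly
    annotated surface in the same document is annotated likewise (short forms
    match case-sensitively, long forms case-insensitively).
    """
    for sentence in corpus.sentences:
        for pair in extract_abbreviations(sentence):
            existing_sf = sentence.tree.get(*pair.short_span)
            existing_lf = sentence.tree.get(*pair.long_span)
            if (existing_sf is None) == (existing_lf is None):
                continue  # neither or both already annotated
            if existing_lf is not None:
                donor, new_span, surface, case_sensitive = (
                    existing_lf, pair.short_span, pair.short_text, True
                )
            else:
                donor, new_span, surface, case_sensitive = (
                    existing_sf, pair.long_span, pair.long_text, False
                )
            new_ann = Annotation(
                start=new_span[0],
                end=new_span[1],
                ids=list(donor.ids),
                provenance=Provenance.ABBREVIATION,
                token_span=sentence.token_span_for(*new_span),
            )
            sentence.tree.insert(new_ann)
            _annotate_later_occurrences(
                corpus, sentence, new_span, surface, list(donor.ids), case_sensitive
            )
    return corpus


def _annotate_later_occurrences(
    corpus: Corpus,
    from_sentence: Sentence,
    from_span: Tuple[int, int],
    surface: str,
    ids,
    case_sensitive: bool,
) -> None:
    abs_after = from_sentence.start + from_span[0]
    needle = surface if case_sensitive else surface.lower()
    for s in corpus.sentences:
        hay = s.text if case_sensitive else s.text.lower()
        pos = 0
        while True:
            hit = hay.find(needle, pos)
            if hit < 0:
                break
            pos = hit + 1
            end = hit + len(surface)
            if s.start + hit <= abs_after:
                continue
            if s.token_span_for(hit, end) is None:
                continue  # must align with token boundaries
            s.tree.insert(
                Annotation(
                    start=hit,
                    end=end,
                    ids=list(ids),
                    provenance=Provenance.ABBREVIATION,
                    token_span=s.token_span_for(hit, end),
                )
            )


# -- disambiguation strategies -----------------------------------------------


def prune_by_depth(tree: ConceptTree, max_depth: int) -> ConceptTree:
    """Remove every annotation deeper than ``max_depth`` (whole subtrees:
    a child of a removed node is necessarily deeper than the limit)."""
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    keep = [a for a in tree.traverse() if tree.depth_of(a) <= max_depth]
    tree.replace(keep)
    return tree


def remove_nested_same_group(tree: ConceptTree) -> ConceptTree:
    """Remove annotations nested inside a larger annotation of the same
    semantic group (any proper ancestor sharing at least one group counts);
    children of removed nodes are promoted."""
    condemned = []
    for ann in tree.traverse():
        own = set(ann.groups)
        for anc in tree.ancestors_of(ann):
            if own & set(anc.groups):
                condemned.append(ann)
                break
    for ann in condemned:
        tree.remove(ann)
    return tree


def filter_by_priority(tree: ConceptTree, group_order: Sequence[str]) -> ConceptTree:
    """Resolve every nesting and intersection by a prioritized group list.

    While any two annotations overlap, the one whose best (highest-priority)
    semantic group ranks lower is removed (children promoted); ties keep the
    larger span, then the leftmost.  Groups absent from ``group_order`` rank
    after the listed ones, in order of first appearance in the tree.
    Terminates with pairwise disjoint, depth-1 annotations.
    """
    rank = {g: i for i, g in enumerate(group_order)}
    nxt = len(rank)
    for ann in tree.traverse():
        for g in ann.groups:
            if g not in rank:
                rank[g] = nxt
                nxt += 1

    def best_rank(a: Annotation) -> int:
        ranks = [rank[g] for g in a.groups]
        return min(ranks) if ranks else nxt  # id-less nodes rank last

    while True:
        order = tree.traverse()  # pre-order conflict scan
        conflict = None
        for i, a in enumerate(order):
            for b in order[i + 1:]:
                if a.overlaps(b):
                    conflict = (a, b)
                    break
            if conflict:
                break
        if conflict is None:
            return tree
        a, b = conflict
        ra, rb = best_rank(a), best_rank(b)
        if ra != rb:
            loser = a if ra > rb else b
        elif (a.end - a.start) != (b.end - b.start):
            loser = a if (a.end - a.start) < (b.end - b.start) else b
        else:
            loser = b if a.start <= b.start else a  # keep leftmost
        tree.remove(loser)
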