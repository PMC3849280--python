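"""Domain model shared by every pipeline stage.

A document (:class:`Corpus`) is a sequence of :class:`Sentence` objects, each
carrying its tokens and a :class:`ConceptTree` of :class:`Annotation` nodes.
The tree is the central container of the framework: heterogeneous biomedical
concepts routinely nest ("breast" inside "breast cancer") or intersect, and a
per-sentence hierarchy keeps all of them, together with their identifiers,
without forcing an early disambiguation decision.

Concept identifiers are quadruples ``source:id:type:group`` naming a concept
in an external resource (e.g. ``NCBI:10114:species:SPEC`` for the genus
*Rattus* in the NCBI Taxonomy).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple


class MalformedIdentifierError(ValueError):
    """Raised when an identifier string cannot be parsed into its quadruple."""

    def __init__(self, raw: str):
        self.raw = raw
        super().__init__(f"malformed identifier (need source:id:type:group): {raw!r}")


@dataclass(frozen=True)
class Identifier:
    """Concept identifier quadruple.

    ``source`` names the external resource, ``id`` is the resource-local
    identifier (it may itself contain colons, e.g. GO accessions), ``type``
    is the fine-grained semantic type (may be empty) and ``group`` the coarse
    semantic group (PRGE, DISO, SPEC, ANAT, ...).
    """

    source: str
    id: str
    type: str
    group: str

    def __post_init__(self) -> None:
        if not self.source:
            raise ValueError("identifier source must be non-empty")
        if not self.group:
            raise ValueError("identifier group must be non-empty")

    def __str__(self) -> str:
        return f"{self.source}:{self.id}:{self.type}:{self.group}"


def parse_identifier(s: str) -> Identifier:
    """Parse ``source:id:type:group`` into an :class:`Identifier`.

    The middle field is greedy: an id that itself contains colons (such as
    ``GO:0005634``) survives because source is the first colon-field, group
    the last and type the second-to-last.
    """
    parts = s.split(":")
    if len(parts) < 4:
        raise MalformedIdentifierError(s)
    return Identifier(parts[0], ":".join(parts[1:-2]), parts[-2], parts[-1])


def format_ids(ids: Iterable[Identifier]) -> str:
    """Serialize identifiers pipe-joined, input order kept, duplicates dropped."""
    seen = []
    for i in ids:
        if i not in seen:
            seen.append(i)
    return "|".join(str(i) for i in seen)


def parse_ids(s: str) -> List[Identifier]:
    """Inverse of :func:`format_ids` (empty string yields an empty list)."""
    if not s:
        return []
    return [parse_identifier(part) for part in s.split("|")]


class Provenance(enum.Enum):
    DICTIONARY = "DICTIONARY"
    ML = "ML"
    ABBREVIATION = "ABBREVIATION"


@dataclass
class Token:
    """One token of a sentence: ordinal index, sentence-relative character
    extent (0-based, end-exclusive) and surface string.  The linguistic
    layers (lemma, POS, chunk) stay ``None`` until a provider fills them."""

    index: int
    start: int
    end: int
    surface: str
    lemma: Optional[str] = None
    pos: Optional[str] = None
    chunk: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"token extent must be non-empty: ({self.start},{self.end})")


@dataclass
class Annotation:
    """A concept mention: a character span within a sentence plus the set of
    identifiers attached to it.  ``ids`` is an ordered, de-duplicated list and
    may mix semantic groups (that is exactly how ambiguity is represented)."""

    start: int
    end: int
    ids: List[Identifier] = field(default_factory=list)
    provenance: Provenance = Provenance.DICTIONARY
    token_span: Optional[Tuple[int, int]] = None  # (first, last) token index

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"annotation extent must be non-empty: ({self.start},{self.end})")
        self.ids = _dedupe(self.ids)

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)

    @property
    def groups(self) -> List[str]:
        """Semantic groups of this node = group fields over its identifiers."""
        out: List[str] = []
        for i in self.ids:
            if i.group not in out:
                out.append(i.group)
        return out

    def merge_ids(self, ids: Iterable[Identifier]) -> None:
        for i in ids:
            if i not in self.ids:
                self.ids.append(i)

    def contains(self, other: "Annotation") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Annotation") -> bool:
        return self.start < other.end and other.start < self.end


def _dedupe(ids: Sequence[Identifier]) -> List[Identifier]:
    out: List[Identifier] = []
    for i in ids:
        if i not in out:
            out.append(i)
    return out


class TraversalOrder(enum.Enum):
    LEVEL = "LEVEL"
    PRE = "PRE"
    POST = "POST"


class AnnotationNotFoundError(KeyError):
    pass


@dataclass
class TreeNode:
    """Structural view of one tree position; built on demand by ConceptTree."""

    annotation: Optional[Annotation]  # None for the virtual root
    depth: int
    parent: Optional["TreeNode"] = None
    children: List["TreeNode"] = field(default_factory=list)


class ConceptTree:
    """Per-sentence hierarchy of annotations.

    The tree stores a flat set of annotations with pairwise distinct spans and
    derives the hierarchy canonically: nodes are ordered by (start asc, end
    desc) and each node hangs under the nearest preceding node that contains
    it, the virtual root otherwise.  Annotations that intersect without
    containment therefore end up as siblings under their lowest common
    containing node.  Because the structure is a pure function of the span
    set, inserting any permutation of the same annotations yields the same
    tree, and equal-span inserts merge identifier lists in place.
    """

    def __init__(self, length: int):
        self.length = length
        self._annotations: List[Annotation] = []

    # -- mutation -----------------------------------------------------------

    def insert(self, ann: Annotation) -> Annotation:
        """Sorted insert; returns the node that now carries ``ann``'s ids."""
        if ann.start < 0 or ann.end > self.length:
            raise ValueError(
                f"annotation ({ann.start},{ann.end}) outside sentence [0,{self.length})"
            )
        for existing in self._annotations:
            if existing.span == ann.span:
                existing.merge_ids(ann.ids)
                return existing
        self._annotations.append(ann)
        self._annotations.sort(key=lambda a: (a.start, -a.end))
        return ann

    def remove(self, ann: Annotation) -> None:
        """Sorted delete: the node is removed and its children are promoted
        to its parent (promotion falls out of the canonical construction)."""
        for existing in self._annotations:
            if existing is ann or existing.span == ann.span:
                self._annotations.remove(existing)
                return
        raise AnnotationNotFoundError(f"annotation ({ann.start},{ann.end}) not in tree")

    def discard_subtree(self, ann: Annotation) -> None:
        """Remove a node together with every descendant."""
        node = self._find_node(ann)
        doomed: List[Annotation] = []

        def collect(n: TreeNode) -> None:
            if n.annotation is not None:
                doomed.append(n.annotation)
            for c in n.children:
                collect(c)

        collect(node)
        self._annotations = [a for a in self._annotations if a not in doomed]

    def replace(self, annotations: Iterable[Annotation]) -> None:
        self._annotations = []
        for a in annotations:
            self.insert(a)

    # -- structure ----------------------------------------------------------

    @property
    def root(self) -> TreeNode:
        """Build the canonical structure: stack-based nesting over the sorted
        annotation list (start asc, end desc)."""
        root = TreeNode(annotation=None, depth=0)
        stack: List[TreeNode] = [root]
        for ann in self._annotations:
            while stack[-1].annotation is not None and not stack[-1].annotation.contains(ann):
                stack.pop()
            parent = stack[-1]
            node = TreeNode(annotation=ann, depth=parent.depth + 1, parent=parent)
            parent.children.append(node)
            stack.append(node)
        return root

    def depth_of(self, ann: Annotation) -> int:
        return self._find_node(ann).depth

    def parent_of(self, ann: Annotation) -> Optional[Annotation]:
        return self._find_node(ann).parent.annotation  # type: ignore[union-attr]

    def ancestors_of(self, ann: Annotation) -> List[Annotation]:
        node = self._find_node(ann)
        out: List[Annotation] = []
        p = node.parent
        while p is not None and p.annotation is not None:
            out.append(p.annotation)
            p = p.parent
        return out

    def _find_node(self, ann: Annotation) -> TreeNode:
        def walk(n: TreeNode) -> Optional[TreeNode]:
            if n.annotation is ann or (
                n.annotation is not None and n.annotation.span == ann.span
            ):
                return n
            for c in n.children:
                found = walk(c)
                if found is not None:
                    return found
            return None

        node = walk(self.root)
        if node is None:
            raise AnnotationNotFoundError(f"annotation ({ann.start},{ann.end}) not in tree")
        return node

    # -- traversal ----------------------------------------------------------

    def traverse(self, order: TraversalOrder = TraversalOrder.PRE) -> List[Annotation]:
        root = self.root
        out: List[Annotation] = []
        if order is TraversalOrder.LEVEL:
            queue = list(root.children)
            while queue:
                node = queue.pop(0)
                out.append(node.annotation)  # type: ignore[arg-type]
                queue.extend(node.children)
            return out

        def pre(n: TreeNode) -> None:
            if n.annotation is not None:
                out.append(n.annotation)
            for c in n.children:
                pre(c)

        def post(n: TreeNode) -> None:
            for c in n.children:
                post(c)
            if n.annotation is not None:
                out.append(n.annotation)

        (pre if order is TraversalOrder.PRE else post)(root)
        return out

    def __len__(self) -> int:
        return len(self._annotations)

    def __iter__(self) -> Iterator[Annotation]:
        return iter(self.traverse(TraversalOrder.PRE))

    def __contains__(self, ann: Annotation) -> bool:
        return any(a is ann or a.span == ann.span for a in self._annotations)

    def get(self, start: int, end: int) -> Optional[Annotation]:
        for a in self._annotations:
            if a.span == (start, end):
                return a
        return None

    def check_invariants(self) -> None:
        """Assert parent-containment, sibling non-containment and span
        uniqueness; used liberally by the test-suite after mutations."""
        spans = [a.span for a in self._annotations]
        assert len(spans) == len(set(spans)), "duplicate spans in tree"

        def walk(n: TreeNode) -> None:
            for c in n.children:
                if n.annotation is not None:
                    assert n.annotation.contains(c.annotation), "child escapes parent extent"
                walk(c)
            for i, a in enumerate(n.children):
                for b in n.children[i + 1:]:
                    assert not a.annotation.contains(b.annotation), "sibling containment"
                    assert not b.annotation.contains(a.annotation), "sibling containment"

        walk(self.root)


@dataclass
class Sentence:
    """One sentence: ordinal ``sid``, document-absolute character extent,
    text, tokens and its concept tree."""

    sid: int
    start: int
    end: int
    text: str
    tokens: List[Token] = field(default_factory=list)
    tree: ConceptTree = None  # type: ignore[assignment]
    parsed_level: "ParsingLevel" = None  # type: ignore[assignment]  # noqa: F821

    def __post_init__(self) -> None:
        if self.tree is None:
            self.tree = ConceptTree(len(self.text))
        if self.parsed_level is None:
            from .nlp import ParsingLevel  # deferred: nlp imports Token from here

            self.parsed_level = ParsingLevel.TOKENIZATION
        for t in self.tokens:
            if t.end > len(self.text):
                raise ValueError("token extent outside sentence text")

    def annotation_text(self, ann: Annotation) -> str:
        return self.text[ann.start:ann.end]

    def token_span_for(self, start: int, end: int) -> Optional[Tuple[int, int]]:
        """Token index span whose boundaries are exactly (start, end), if any."""
        first = last = None
        for t in self.tokens:
            if t.start == start:
                first = t.index
            if t.end == end:
                last = t.index
        if first is None or last is None or last < first:
            return None
        return (first, last)


@dataclass
class Corpus:
    """A processed document: identifier, the text that was actually analysed
    (concatenated regions of interest) and its sentences.  ``roi_map`` lists
    the processed regions in corpus-text coordinates; ``source`` keeps a
    handle on the original input for writers that re-embed annotations."""

    doc_id: str
    text: str
    sentences: List[Sentence] = field(default_factory=list)
    roi_map: List[Tuple[int, int]] = field(default_factory=list)
    source: Optional[object] = None  # io_formats.RoiDocument when read from XML

    def annotations(self) -> List[Tuple[Sentence, Annotation]]:
        out = []
        for s in self.sentences:
            for a in s.tree:
                out.append((s, a))
        return out

    def n_annotations(self) -> int:
        return sum(len(s.tree) for s in self.sentences)
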