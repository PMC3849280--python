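"""Readers and writers for the standard annotation formats.

Readers turn an input document into a :class:`RoiDocument`: the original
text plus the ordered regions of interest (ROI) that downstream modules are
allowed to analyse.  The raw reader declares the whole text interesting; the
XML reader selects the content of user-named tags (e.g. ``ArticleTitle`` and
``AbstractText`` in Pubmed records), unescaping entities while keeping an
exact offset map back to the source so that annotations can later be
re-embedded without touching a single non-ROI byte.

Writers serialize a processed :class:`~biocr.core.Corpus`:

* A1 standoff (brat-compatible), with identifiers on AnnotatorNotes lines;
* CoNLL-style TSV with one BIO label column per tree depth, so nested and
  intersected annotations survive the token-per-line layout;
* inline XML ``<e id="...">`` elements (two nesting levels at most);
* JSON mirroring the concept tree;
* an indented plain-text tree format, the most human-readable of the set.

All offsets in the emitted files are document-absolute and index the
processed text exactly.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, IO, Iterable, List, Optional, Set, Tuple

from lxml import etree

from .core import (
    Annotation,
    ConceptTree,
    Corpus,
    Identifier,
    Provenance,
    Sentence,
    TraversalOrder,
    format_ids,
    parse_ids,
)

logger = logging.getLogger(__name__)


class XmlParseError(ValueError):
    pass


class A1ParseError(ValueError):
    pass


# -- readers -----------------------------------------------------------------


@dataclass
class Roi:
    """One region of interest: unescaped text plus, per character, the
    half-open source extent it came from (entities map several-to-one)."""

    text: str
    src_starts: List[int]
    src_ends: List[int]
    tag: Optional[str] = None


@dataclass
class RoiDocument:
    """Original document plus its ordered, non-overlapping ROI regions."""

    source: str
    rois: List[Roi] = field(default_factory=list)
    is_xml: bool = False

    @property
    def text(self) -> str:
        """Processed text: ROI texts joined with a newline separator."""
        return "\n".join(r.text for r in self.rois)

    def roi_spans(self) -> List[Tuple[int, int]]:
        """ROI extents in processed-text coordinates."""
        spans = []
        pos = 0
        for r in self.rois:
            spans.append((pos, pos + len(r.text)))
            pos += len(r.text) + 1
        return spans

    def source_extent(self, text_pos: int) -> Tuple[int, int]:
        """Map a processed-text position to its source extent."""
        for (s, e), roi in zip(self.roi_spans(), self.rois):
            if s <= text_pos < e:
                i = text_pos - s
                return (roi.src_starts[i], roi.src_ends[i])
        raise IndexError(f"position {text_pos} is not inside any ROI")


def read_raw(text: str) -> RoiDocument:
    """All the input text is of interest: a single identity-mapped ROI."""
    roi = Roi(
        text=text,
        src_starts=list(range(len(text))),
        src_ends=list(range(1, len(text) + 1)),
    )
    return RoiDocument(source=text, rois=[roi], is_xml=False)


_XML_TOKEN = re.compile(
    r"<!--.*?-->"                # comment
    r"|<!\[CDATA\[.*?\]\]>"      # CDATA section
    r"|<\?.*?\?>"                # processing instruction / declaration
    r"|<!DOCTYPE[^>]*>"          # doctype
    r"|<(/?)([A-Za-z_][\w.:-]*)((?:[^>\"']|\"[^\"]*\"|'[^']*')*?)(/?)>",
    re.DOTALL,
)
_ENTITY = re.compile(r"&(?:#x?[0-9A-Fa-f]+|\w+);")
_NAMED_ENTITIES = {"&amp;": "&", "&lt;": "<", "&gt;": ">", "&quot;": '"', "&apos;": "'"}


def _unescape_entity(ent: str) -> str:
    if ent in _NAMED_ENTITIES:
        return _NAMED_ENTITIES[ent]
    if ent.startswith("&#x") or ent.startswith("&#X"):
        return chr(int(ent[3:-1], 16))
    if ent.startswith("&#"):
        return chr(int(ent[2:-1]))
    return ent  # unknown named entity: keep verbatim


def read_xml(xml: str, tags: Iterable[str]) -> RoiDocument:
    """Select the content of the named elements as regions of interest.

    One ROI per occurrence of each named tag, in document order; when a
    selected tag occurs inside another selected tag, only the outermost
    occurrence contributes a region.  Entity references inside a region are
    unescaped with an exact offset map back to the source; markup of child
    elements contributes no text.  Malformed XML raises
    :class:`XmlParseError` with the parser's location message.
    """
    tags = set(tags)
    if not tags:
        raise ValueError("at least one tag of interest is required")
    try:
        etree.fromstring(xml.encode("utf-8"), parser=etree.XMLParser(resolve_entities=False))
    except etree.XMLSyntaxError as exc:
        raise XmlParseError(str(exc)) from exc

    rois: List[Roi] = []
    stack: List[str] = []
    roi_open_depth: Optional[int] = None  # stack depth where the current ROI began
    current: Optional[Roi] = None
    pos = 0

    def emit_text(seg_start: int, seg_end: int) -> None:
        assert current is not None
        i = seg_start
        for ent in _ENTITY.finditer(xml, seg_start, seg_end):
            for k in range(i, ent.start()):
                current.text += xml[k]
                current.src_starts.append(k)
                current.src_ends.append(k + 1)
            ch = _unescape_entity(ent.group(0))
            for c in ch:
                current.text += c
                current.src_starts.append(ent.start())
                current.src_ends.append(ent.end())
            i = ent.end()
        for k in range(i, seg_end):
            current.text += xml[k]
            current.src_starts.append(k)
            current.src_ends.append(k + 1)

    for m in _XML_TOKEN.finditer(xml):
        if current is not None:
            emit_text(pos, m.start())
        pos = m.end()
        if m.group(2) is None:
            continue  # comment / PI / CDATA / doctype
        closing, name, _attrs, selfclose = m.group(1), m.group(2), m.group(3), m.group(4)
        if closing:
            while stack and stack[-1] != name:
                stack.pop()  # tolerate recoverable nesting slips; lxml already validated
            if stack:
                stack.pop()
            if roi_open_depth is not None and len(stack) < roi_open_depth:
                rois.append(current)  # type: ignore[arg-type]
                current = None
                roi_open_depth = None
        elif selfclose:
            if name in tags and roi_open_depth is None:
                rois.append(Roi(text="", src_starts=[], src_ends=[], tag=name))
        else:
            stack.append(name)
            if name in tags and roi_open_depth is None:
                current = Roi(text="", src_starts=[], src_ends=[], tag=name)
                roi_open_depth = len(stack)
    return RoiDocument(source=xml, rois=rois, is_xml=True)


# -- A1 standoff -------------------------------------------------------------

UNKNOWN_GROUP = "UNKN"


def _a1_group(ann: Annotation) -> str:
    groups = ann.groups
    return groups[0] if groups else UNKNOWN_GROUP


def write_a1(corpus: Corpus, stream: IO[str]) -> None:
    """Write brat-style A1 standoff.

    One ``T{n}<TAB>{GROUP} {start} {end}<TAB>{text}`` line per tree node in
    pre-order with document-absolute offsets (a multi-group node uses its
    first group), followed by one AnnotatorNotes line per identified node
    carrying the pipe-joined identifier list.
    """
    n = 0
    notes: List[str] = []
    for sentence in corpus.sentences:
        for ann in sentence.tree.traverse(TraversalOrder.PRE):
            n += 1
            s = sentence.start + ann.start
            e = sentence.start + ann.end
            text = corpus.text[s:e]
            stream.write(f"T{n}\t{_a1_group(ann)} {s} {e}\t{text}\n")
            if ann.ids:
                notes.append(f"#{n}\tAnnotatorNotes T{n}\t{format_ids(ann.ids)}\n")
    for line in notes:
        stream.write(line)


@dataclass
class A1Annotation:
    """One standoff annotation as read back from an A1 file."""

    tid: str
    group: str
    start: int
    end: int
    text: str
    ids: List[Identifier] = field(default_factory=list)


_T_LINE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_NOTE_LINE = re.compile(r"^#\d+\tAnnotatorNotes (T\d+)\t(.*)$")


def read_a1(stream: IO[str]) -> List[A1Annotation]:
    """Read A1 standoff back into annotations (inverse of :func:`write_a1`)."""
    by_tid: Dict[str, A1Annotation] = {}
    order: List[A1Annotation] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("T"):
            m = _T_LINE.match(line)
            if not m:
                raise A1ParseError(f"line {lineno}: malformed T line: {line!r}")
            ann = A1Annotation(
                tid=m.group(1),
                group=m.group(2),
                start=int(m.group(3)),
                end=int(m.group(4)),
                text=m.group(5),
            )
            by_tid[ann.tid] = ann
            order.append(ann)
        elif line.startswith("#"):
            m = _NOTE_LINE.match(line)
            if not m:
                raise A1ParseError(f"line {lineno}: malformed note line: {line!r}")
            tid = m.group(1)
            if tid not in by_tid:
                raise A1ParseError(f"line {lineno}: note for unknown annotation {tid}")
            by_tid[tid].ids = parse_ids(m.group(2))
        else:
            raise A1ParseError(f"line {lineno}: unrecognized line: {line!r}")
    return order


# -- CoNLL -------------------------------------------------------------------


def write_conll(corpus: Corpus, stream: IO[str]) -> None:
    """Write CoNLL-style TSV with per-depth BIO columns.

    One token per line — index (1-based), surface, lemma, POS, chunk — then
    one BIO column per tree depth present in the sentence, so annotations at
    depth *k* land in label column *k*.  Complex identifiers do not fit the
    format, so only semantic groups are emitted.  Sentences are separated by
    a blank line.
    """
    for sentence in corpus.sentences:
        depths = [sentence.tree.depth_of(a) for a in sentence.tree.traverse()]
        n_cols = max(depths, default=1)
        labels = [["O"] * len(sentence.tokens) for _ in range(n_cols)]
        for ann in sentence.tree.traverse(TraversalOrder.PRE):
            col = sentence.tree.depth_of(ann) - 1
            span = ann.token_span or sentence.token_span_for(ann.start, ann.end)
            if span is None:
                logger.warning("annotation (%d,%d) off token boundaries; skipped in CoNLL",
                               ann.start, ann.end)
                continue
            first, last = span
            group = _a1_group(ann)
            if labels[col][first] != "O":
                continue  # same-depth collision (intersected siblings): keep first
            labels[col][first] = f"B-{group}"
            for k in range(first + 1, last + 1):
                labels[col][k] = f"I-{group}"
        for t in sentence.tokens:
            fields = [
                str(t.index + 1),
                t.surface,
                t.lemma or "_",
                t.pos or "_",
                t.chunk or "_",
            ] + [labels[c][t.index] for c in range(n_cols)]
            stream.write("\t".join(fields) + "\n")
        stream.write("\n")


# -- inline XML --------------------------------------------------------------

MAX_INLINE_DEPTH = 2


def _inline_kept(tree: ConceptTree) -> List[Tuple[Annotation, int]]:
    """Annotations representable inline: depth <= 2, and no crossing with an
    annotation already kept (overlapping tags cannot nest in XML)."""
    kept: List[Tuple[Annotation, int]] = []
    for ann in tree.traverse(TraversalOrder.PRE):
        depth = tree.depth_of(ann)
        if depth > MAX_INLINE_DEPTH:
            logger.warning("annotation (%d,%d) at depth %d dropped from inline XML",
                           ann.start, ann.end, depth)
            continue
        crossing = any(
            a.overlaps(ann) and not a.contains(ann) and not ann.contains(a)
            for a, _ in kept
        )
        if crossing:
            logger.warning("annotation (%d,%d) intersects a kept annotation; "
                           "dropped from inline XML", ann.start, ann.end)
            continue
        kept.append((ann, depth))
    return kept


def _insertions_for(corpus: Corpus) -> List[Tuple[int, int, int, str]]:
    """(doc_pos, kind, tiebreak, markup) insertion records; kind 0 = close
    before kind 1 = open at equal positions."""
    out: List[Tuple[int, int, int, str]] = []
    for sentence in corpus.sentences:
        for ann, _depth in _inline_kept(sentence.tree):
            s = sentence.start + ann.start
            e = sentence.start + ann.end
            open_tag = f'<e id="{_attr_escape(format_ids(ann.ids))}">'
            # opens: outer first (end desc); closes: inner first (start desc)
            out.append((s, 1, -e, open_tag))
            out.append((e, 0, -s, "</e>"))
    out.sort(key=lambda r: (r[0], r[1], r[2]))
    return out


def _attr_escape(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace('"', "&quot;")


def write_inline_xml(corpus: Corpus, stream: IO[str]) -> None:
    """Write the document with annotations embedded as ``<e id="...">``
    elements (at most two nesting levels; deeper or crossing annotations are
    dropped with a logged warning).

    When the corpus was read from XML, the annotations are re-embedded into
    the original document: every byte outside the regions of interest is
    preserved exactly.  For raw input the annotated processed text is
    emitted as-is, so stripping the ``<e>`` tags recovers the original text.
    """
    insertions = _insertions_for(corpus)
    doc = corpus.source if isinstance(corpus.source, RoiDocument) else None
    if doc is not None and doc.is_xml:
        records = []
        for pos, kind, tie, markup in insertions:
            if kind == 1:
                src = doc.source_extent(pos)[0]
            else:
                src = doc.source_extent(pos - 1)[1]
            records.append((src, kind, tie, markup))
        records.sort(key=lambda r: (r[0], r[1], r[2]))
        text = doc.source
    else:
        records = insertions
        text = corpus.text
    out: List[str] = []
    prev = 0
    for pos, _kind, _tie, markup in records:
        out.append(text[prev:pos])
        out.append(markup)
        prev = pos
    out.append(text[prev:])
    stream.write("".join(out))


# -- JSON and indented tree format -------------------------------------------


def _term_dict(corpus: Corpus, sentence: Sentence, node, counter: List[int]) -> dict:
    ann = node.annotation
    counter[0] += 1
    s = sentence.start + ann.start
    e = sentence.start + ann.end
    return {
        "id": f"T{counter[0]}",
        "start": s,
        "end": e,
        "text": corpus.text[s:e],
        "ids": [str(i) for i in ann.ids],
        "children": [_term_dict(corpus, sentence, c, counter) for c in node.children],
    }


def write_json(corpus: Corpus, stream: IO[str]) -> None:
    """JSON mirror of the concept trees: one object per sentence with its
    document-absolute extent, text and recursively nested terms."""
    counter = [0]
    payload = [
        {
            "id": s.sid,
            "start": s.start,
            "end": s.end,
            "text": s.text,
            "terms": [_term_dict(corpus, s, c, counter) for c in s.tree.root.children],
        }
        for s in corpus.sentences
    ]
    json.dump(payload, stream, ensure_ascii=False, indent=2)
    stream.write("\n")


def write_neji(corpus: Corpus, stream: IO[str]) -> None:
    """Indented plain-text tree format.

    Per sentence one ``S{sid}\\t{start}\\t{end}\\t{text}`` header, then one
    line per annotation in pre-order, prefixed by depth-1 TAB characters:
    ``T{tid}\\t{start}\\t{end}\\t{text}\\t{pipe-joined ids}``.
    """
    tid = 0
    for sentence in corpus.sentences:
        stream.write(f"S{sentence.sid}\t{sentence.start}\t{sentence.end}\t{sentence.text}\n")
        for ann in sentence.tree.traverse(TraversalOrder.PRE):
            tid += 1
            depth = sentence.tree.depth_of(ann)
            s = sentence.start + ann.start
            e = sentence.start + ann.end
            prefix = "\t" * (depth - 1)
            stream.write(
                f"{prefix}T{tid}\t{s}\t{e}\t{corpus.text[s:e]}\t{format_ids(ann.ids)}\n"
            )
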