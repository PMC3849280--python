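"""Evaluation harness: span matching, identifier matching, micro P/R/F1.

Span agreement between a prediction and a gold annotation comes in five
flavours — exact (both boundaries), left (start), right (end), shared
(either boundary) and overlap (any non-empty intersection) — because a
non-exact boundary rarely means the wrong concept: annotation guidelines
disagree on suffixes like "gene"/"protein", organism prefixes and Greek
letters.  Identifier agreement is either exact (the prediction carries
exactly the gold identifier set) or contains (the gold identifiers are among
those predicted).

Counts are micro-averaged: true/false positives and false negatives are
pooled over all documents before computing precision, recall and F1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .core import Annotation, Corpus, Identifier
from .io_formats import A1Annotation


class SpanStrategy(enum.Enum):
    EXACT = "exact"
    LEFT = "left"
    RIGHT = "right"
    SHARED = "shared"
    OVERLAP = "overlap"


class IdStrategy(enum.Enum):
    EXACT = "exact"
    CONTAINS = "contains"


Span = Tuple[int, int]


def span_accept(pred: Span, gold: Span, strategy: SpanStrategy) -> bool:
    """Span acceptance predicate; both spans share one coordinate frame."""
    ps, pe = pred
    gs, ge = gold
    if strategy is SpanStrategy.EXACT:
        return ps == gs and pe == ge
    if strategy is SpanStrategy.LEFT:
        return ps == gs
    if strategy is SpanStrategy.RIGHT:
        return pe == ge
    if strategy is SpanStrategy.SHARED:
        return ps == gs or pe == ge
    return ps < ge and gs < pe  # OVERLAP


def id_accept(
    pred_ids: Sequence[Identifier],
    gold: Union[Identifier, Sequence[Identifier]],
    strategy: IdStrategy,
) -> bool:
    """Identifier acceptance predicate.

    EXACT requires the predicted identifier list to be exactly the gold one
    (for a single gold identifier: exactly one prediction, and it matches);
    CONTAINS requires every gold identifier to appear among the predictions.
    """
    gold_ids = [gold] if isinstance(gold, Identifier) else list(gold)
    if strategy is IdStrategy.EXACT:
        return len(pred_ids) == len(gold_ids) and set(pred_ids) == set(gold_ids)
    return all(g in pred_ids for g in gold_ids)


@dataclass
class EvaluationCounts:
    """Pooled TP/FP/FN with derived micro-averaged metrics.

    Zero denominators resolve to 0 (P when nothing was predicted, R when
    there is no gold, F1 when both vanish) so empty outputs degrade
    monotonically instead of raising.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def __iadd__(self, other: "EvaluationCounts") -> "EvaluationCounts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self


@dataclass
class EvalUnit:
    """Format-neutral annotation used by the harness."""

    start: int
    end: int
    group: str
    ids: List[Identifier] = field(default_factory=list)

    @property
    def span(self) -> Span:
        return (self.start, self.end)


def corpus_to_units(corpus: Corpus) -> List[EvalUnit]:
    """Flatten a corpus's trees into document-absolute evaluation units."""
    units = []
    for sentence, ann in corpus.annotations():
        groups = ann.groups
        units.append(
            EvalUnit(
                start=sentence.start + ann.start,
                end=sentence.start + ann.end,
                group=groups[0] if groups else "UNKN",
                ids=list(ann.ids),
            )
        )
    return units


def a1_to_units(annotations: Iterable[A1Annotation]) -> List[EvalUnit]:
    return [
        EvalUnit(start=a.start, end=a.end, group=a.group, ids=list(a.ids))
        for a in annotations
    ]


def evaluate_document(
    pred: Sequence[EvalUnit],
    gold: Sequence[EvalUnit],
    span_strategy: SpanStrategy,
    id_strategy: Optional[IdStrategy] = None,
    group_aware: bool = True,
) -> EvaluationCounts:
    """One-to-one greedy matching within a single document.

    Golds are visited in document order; each takes the accepting,
    still-unmatched prediction with the smallest start (largest span on
    ties).  A pair must agree on span strategy, semantic group (when
    ``group_aware``) and — when an identifier strategy is given — on
    identifiers.  TP = matched pairs, FP = unmatched predictions,
    FN = unmatched golds.
    """
    preds = sorted(pred, key=lambda u: (u.start, -(u.end - u.start)))
    matched = [False] * len(preds)
    tp = 0
    for g in sorted(gold, key=lambda u: (u.start, u.end)):
        for i, p in enumerate(preds):
            if matched[i]:
                continue
            if group_aware and p.group != g.group and g.group not in {
                ident.group for ident in p.ids
            }:
                continue
            if not span_accept(p.span, g.span, span_strategy):
                continue
            if id_strategy is not None and not id_accept(p.ids, g.ids, id_strategy):
                continue
            matched[i] = True
            tp += 1
            break
    return EvaluationCounts(tp=tp, fp=matched.count(False), fn=len(gold) - tp)


def evaluate(
    pred_docs: Mapping[str, Sequence[EvalUnit]],
    gold_docs: Mapping[str, Sequence[EvalUnit]],
    span_strategy: SpanStrategy,
    id_strategy: Optional[IdStrategy] = None,
    group_aware: bool = True,
) -> EvaluationCounts:
    """Micro-averaged evaluation: counts pooled over all documents before
    computing P/R/F1.  Documents present on only one side count as all-FP
    or all-FN."""
    counts = EvaluationCounts()
    for doc_id in sorted(set(pred_docs) | set(gold_docs)):
        counts += evaluate_document(
            pred_docs.get(doc_id, []),
            gold_docs.get(doc_id, []),
            span_strategy,
            id_strategy,
            group_aware,
        )
    return counts


def evaluate_by_group(
    pred_docs: Mapping[str, Sequence[EvalUnit]],
    gold_docs: Mapping[str, Sequence[EvalUnit]],
    span_strategy: SpanStrategy,
    id_strategy: Optional[IdStrategy] = None,
) -> Dict[str, EvaluationCounts]:
    """Per-semantic-group counts plus an ``overall`` pooled entry."""
    groups = sorted(
        {u.group for units in list(pred_docs.values()) + list(gold_docs.values()) for u in units}
    )
    report: Dict[str, EvaluationCounts] = {}
    for g in groups:
        report[g] = evaluate(
            {d: [u for u in us if u.group == g] for d, us in pred_docs.items()},
            {d: [u for u in us if u.group == g] for d, us in gold_docs.items()},
            span_strategy,
            id_strategy,
        )
    overall = EvaluationCounts()
    for c in report.values():
        overall += c
    report["overall"] = overall
    return report
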