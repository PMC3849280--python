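"""Abbreviation resolution and the three disambiguation strategies."""

import random

import pytest

from biocr.core import Annotation, ConceptTree, Corpus, Provenance
from biocr.nlp import tokenize
from biocr.postprocess import (
    extend_by_abbreviations,
    extract_abbreviations,
    filter_by_priority,
    prune_by_depth,
    remove_nested_same_group,
)

from conftest import ident, make_sentence, tree_shape


class TestExtractAbbreviations:
    def test_tcf_pair(self):
        s = make_sentence("the T cell factor (TCF) pathway")
        pairs = extract_abbreviations(s)
        assert len(pairs) == 1
        assert pairs[0].short_text == "TCF"
        assert pairs[0].long_text == "T cell factor"
        assert s.text[slice(*pairs[0].long_span)] == "T cell factor"

    def test_single_char_rejected(self):
        assert extract_abbreviations(make_sentence("some protein(s) here")) == []

    def test_too_many_words_rejected(self):
        s = make_sentence("factor (T cell factor) again")
        assert extract_abbreviations(s) == []

    def test_no_letter_rejected(self):
        assert extract_abbreviations(make_sentence("value (42) given")) == []

    def test_first_char_must_be_alnum(self):
        assert extract_abbreviations(make_sentence("T cell factor (-TCF) x")) == []

    def test_shortest_valid_suffix_chosen(self):
        s = make_sentence("we studied the nuclear factor (NF) complex")
        pairs = extract_abbreviations(s)
        assert len(pairs) == 1
        assert pairs[0].long_text == "nuclear factor"

    def test_subsequence_must_hold(self):
        s = make_sentence("the quick brown dog (XYZ) barked")
        assert extract_abbreviations(s) == []

    def test_planted_pairs_recovered(self):
        rng = random.Random(13)
        consonants, vowels = "bdfgklmnprst", "aeiou"

        def word():
            return "".join(rng.choice(consonants) + rng.choice(vowels)
                           for _ in range(rng.randint(2, 3)))

        for _ in range(40):
            words = [word()]
            while len(words) < 3:
                w = word()
                if w[0] not in {x[0] for x in words}:
                    words.append(w)
            lf = " ".join(words)
            sf = "".join(w[0] for w in words).upper()
            text = f"We studied the {lf} ({sf}) in detail."
            pairs = extract_abbreviations(make_sentence(text))
            assert [(p.long_text, p.short_text) for p in pairs] == [(lf, sf)]


def corpus_of(*sentence_texts):
    sentences = []
    pos = 0
    for i, t in enumerate(sentence_texts):
        sentences.append(make_sentence(t, sid=i, start=pos))
        pos += len(t) + 1
    return Corpus(doc_id="d", text=" ".join(sentence_texts), sentences=sentences)


class TestExtendByAbbreviations:
    PRGE_X = ident(id="X")

    def test_short_form_gains_long_form_ids_and_propagates(self):
        c = corpus_of(
            "the T cell factor (TCF) pathway was active.",
            "Increased TCF activity was then observed.",
        )
        s0 = c.sentences[0]
        lf_span = (s0.text.index("T cell"), s0.text.index(" (TCF)"))
        s0.tree.insert(Annotation(start=lf_span[0], end=lf_span[1], ids=[self.PRGE_X]))
        extend_by_abbreviations(c)
        sf0 = s0.tree.get(s0.text.index("TCF)"), s0.text.index("TCF)") + 3)
        assert sf0 is not None and sf0.ids == [self.PRGE_X]
        assert sf0.provenance is Provenance.ABBREVIATION
        s1 = c.sentences[1]
        sf1 = s1.tree.get(s1.text.index("TCF"), s1.text.index("TCF") + 3)
        assert sf1 is not None and sf1.ids == [self.PRGE_X]

    def test_long_form_gains_short_form_ids(self):
        c = corpus_of("the T cell factor (TCF) pathway.")
        s0 = c.sentences[0]
        sf_start = s0.text.index("TCF)")
        s0.tree.insert(Annotation(start=sf_start, end=sf_start + 3, ids=[self.PRGE_X]))
        extend_by_abbreviations(c)
        lf = s0.tree.get(s0.text.index("T cell"), s0.text.index(" (TCF)"))
        assert lf is not None and lf.ids == [self.PRGE_X]

    def test_neither_form_annotated_no_change(self):
        c = corpus_of("the T cell factor (TCF) pathway.")
        extend_by_abbreviations(c)
        assert c.n_annotations() == 0

    def test_both_forms_annotated_no_duplicates(self):
        c = corpus_of("the T cell factor (TCF) pathway.")
        s0 = c.sentences[0]
        lf_span = (s0.text.index("T cell"), s0.text.index(" (TCF)"))
        sf_start = s0.text.index("TCF)")
        s0.tree.insert(Annotation(start=lf_span[0], end=lf_span[1], ids=[self.PRGE_X]))
        s0.tree.insert(Annotation(start=sf_start, end=sf_start + 3, ids=[self.PRGE_X]))
        before = c.n_annotations()
        extend_by_abbreviations(c)
        assert c.n_annotations() == before

    def test_never_decreases_annotations(self):
        c = corpus_of("the T cell factor (TCF) pathway.", "No mentions here at all.")
        s0 = c.sentences[0]
        s0.tree.insert(Annotation(start=s0.text.index("T cell"),
                                  end=s0.text.index(" (TCF)"), ids=[self.PRGE_X]))
        before = c.n_annotations()
        extend_by_abbreviations(c)
        assert c.n_annotations() >= before


def chain_tree(*spans_groups):
    """Build a tree from (start, end, group) triples."""
    length = max(e for _, e, _ in spans_groups)
    tree = ConceptTree(length)
    nodes = []
    for k, (s, e, g) in enumerate(spans_groups):
        nodes.append(tree.insert(Annotation(start=s, end=e, ids=[ident(id=str(k), group=g)])))
    return tree, nodes


def random_tree(rng, length=20, max_nodes=7):
    tree = ConceptTree(length)
    spans = set()
    for _ in range(rng.randint(0, max_nodes)):
        s = rng.randint(0, length - 2)
        e = rng.randint(s + 1, length)
        if (s, e) in spans:
            continue
        spans.add((s, e))
        group = rng.choice(["PRGE", "DISO", "ANAT"])
        tree.insert(Annotation(start=s, end=e,
                               ids=[ident(id=f"{s}-{e}", group=group)]))
    return tree


class TestPruneByDepth:
    def test_chain_pruned_to_root_level(self):
        tree, (a, b, c) = chain_tree((0, 9, "PRGE"), (0, 6, "DISO"), (0, 3, "ANAT"))
        prune_by_depth(tree, 1)
        assert tree.traverse() == [a]

    def test_depth_at_least_height_is_identity(self):
        tree, _ = chain_tree((0, 9, "PRGE"), (0, 6, "DISO"))
        before = tree_shape(tree)
        prune_by_depth(tree, 5)
        assert tree_shape(tree) == before

    def test_invalid_depth(self):
        tree, _ = chain_tree((0, 9, "PRGE"))
        with pytest.raises(ValueError):
            prune_by_depth(tree, 0)

    def test_census_against_depth_count(self):
        rng = random.Random(19)
        for _ in range(40):
            tree = random_tree(rng)
            for max_depth in (1, 2, 3):
                counts = sum(1 for a in tree.traverse() if tree.depth_of(a) <= max_depth)
                clone = ConceptTree(tree.length)
                for a in tree.traverse():
                    clone.insert(Annotation(start=a.start, end=a.end, ids=list(a.ids)))
                prune_by_depth(clone, max_depth)
                assert len(clone) == counts

    def test_idempotent(self):
        rng = random.Random(23)
        for _ in range(20):
            tree = random_tree(rng)
            prune_by_depth(tree, 2)
            once = tree_shape(tree)
            prune_by_depth(tree, 2)
            assert tree_shape(tree) == once


class TestRemoveNestedSameGroup:
    def test_same_group_inner_removed(self):
        tree, (outer, inner) = chain_tree((0, 10, "PRGE"), (0, 5, "PRGE"))
        remove_nested_same_group(tree)
        assert tree.traverse() == [outer]

    def test_different_group_untouched(self):
        tree, nodes = chain_tree((0, 10, "PRGE"), (0, 5, "DISO"))
        remove_nested_same_group(tree)
        assert len(tree) == 2

    def test_any_ancestor_counts(self):
        tree, (a, b, c) = chain_tree((0, 10, "PRGE"), (0, 7, "DISO"), (0, 5, "PRGE"))
        remove_nested_same_group(tree)
        spans = [x.span for x in tree.traverse()]
        assert (0, 5) not in spans and (0, 7) in spans

    def test_matches_ancestor_chain_oracle(self):
        rng = random.Random(29)
        for _ in range(60):
            tree = random_tree(rng)
            survivors_oracle = {
                a.span
                for a in tree.traverse()
                if not any(set(a.groups) & set(anc.groups)
                           for anc in tree.ancestors_of(a))
            }
            remove_nested_same_group(tree)
            assert {a.span for a in tree.traverse()} == survivors_oracle

    def test_idempotent(self):
        rng = random.Random(31)
        for _ in range(30):
            tree = random_tree(rng)
            remove_nested_same_group(tree)
            once = tree_shape(tree)
            remove_nested_same_group(tree)
            assert tree_shape(tree) == once


class TestFilterByPriority:
    def test_priority_decides_intersections(self):
        tree, _ = chain_tree((0, 5, "PRGE"), (3, 9, "DISO"))
        filter_by_priority(tree, ["PRGE", "DISO"])
        assert [a.span for a in tree.traverse()] == [(0, 5)]

    def test_reversed_priority(self):
        tree, _ = chain_tree((0, 5, "PRGE"), (3, 9, "DISO"))
        filter_by_priority(tree, ["DISO", "PRGE"])
        assert [a.span for a in tree.traverse()] == [(3, 9)]

    def test_tie_keeps_larger_then_leftmost(self):
        tree, _ = chain_tree((0, 8, "PRGE"), (5, 9, "PRGE"))
        filter_by_priority(tree, ["PRGE"])
        assert [a.span for a in tree.traverse()] == [(0, 8)]

    def test_result_is_antichain(self):
        rng = random.Random(37)
        for _ in range(60):
            tree = random_tree(rng)
            filter_by_priority(tree, ["PRGE", "DISO", "ANAT"])
            remaining = tree.traverse()
            assert all(tree.depth_of(a) == 1 for a in remaining)
            for i, a in enumerate(remaining):
                for b in remaining[i + 1:]:
                    assert not a.overlaps(b)

    def test_unlisted_groups_rank_last(self):
        tree, _ = chain_tree((0, 5, "CHED"), (3, 9, "PRGE"))
        filter_by_priority(tree, ["PRGE"])
        assert [a.span for a in tree.traverse()] == [(3, 9)]

    def test_idempotent(self):
        rng = random.Random(41)
        for _ in range(30):
            tree = random_tree(rng)
            filter_by_priority(tree, ["PRGE", "DISO"])
            once = tree_shape(tree)
            filter_by_priority(tree, ["PRGE", "DISO"])
            assert tree_shape(tree) == once


class TestStrategiesPreserveContent:
    def test_no_new_ids_or_span_changes(self):
        rng = random.Random(43)
        for strategy in ("depth", "same_group", "priority"):
            for _ in range(20):
                tree = random_tree(rng)
                before = {a.span: tuple(str(i) for i in a.ids) for a in tree.traverse()}
                if strategy == "depth":
                    prune_by_depth(tree, 2)
                elif strategy == "same_group":
                    remove_nested_same_group(tree)
                else:
                    filter_by_priority(tree, ["PRGE", "DISO", "ANAT"])
                for a in tree.traverse():
                    assert before[a.span] == tuple(str(i) for i in a.ids)
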