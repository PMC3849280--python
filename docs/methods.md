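# Methods

This note documents the models and procedures implemented in `biocr`, the
conventions chosen where several were defensible, and what the synthetic
fixtures do and do not demonstrate.

## Corpus model and the concept tree

A document is processed into a `Corpus` of `Sentence` objects. Character
offsets are 0-based and end-exclusive; annotations are sentence-relative
internally and converted to document-absolute offsets only by the writers.
One unambiguous convention everywhere avoids the classic off-by-one
disagreements between standoff formats.

Each sentence owns a `ConceptTree`. The tree stores a flat set of
annotations with pairwise distinct spans and derives the hierarchy
canonically: annotations are ordered by (start ascending, end descending)
and each hangs under the nearest preceding annotation that contains it.
Consequences worth knowing:

* **Insertion-order invariance.** The structure is a pure function of the
  span set, so any insertion order yields the same tree. An incremental
  "find deepest container, re-parent contained children" insert is
  equivalent for purely nested span sets but becomes order-dependent once
  spans intersect; the canonical construction removes that ambiguity.
* **Intersections.** An annotation that overlaps another without
  containment becomes a sibling under their lowest common containing node.
  When a span is contained in *two* intersecting siblings, it attaches to
  the earlier sibling in the (start asc, end desc) order — a convention,
  applied deterministically.
* **Equal spans merge.** Re-inserting an existing span unions identifier
  lists in place (order-preserving, de-duplicated). Merging is idempotent
  and commutative up to list order.
* A node's semantic groups are the group fields over its identifiers; an
  identifier's `type` may be empty, `source` and `group` may not.

Removal deletes one node; its children are promoted automatically by the
canonical rebuild. `prune_by_depth` removes whole subtrees instead, since
any descendant of a too-deep node is itself too deep.

## Sentence splitting and tokenization

The built-in splitter is rule-based: a run of `.?!` followed by whitespace
and an uppercase letter or digit ends a sentence, unless the token before a
period is in a configurable abbreviation list (`e.g`, `et al.`, `fig`, ...).
Splitting is a contract; corpus-trained splitters can be plugged in, the
default merely guarantees determinism and full coverage of non-whitespace
text.

The tokenizer splits on whitespace and then breaks every non-alphanumeric
symbol — in particular `/`, `-` and `.` — into its own token, so
`N-acetyl-cysteine` yields five tokens and `E.coli` three. Letter–digit
boundaries (`IL2`, `p53`) are never split. Token extents tile the
non-whitespace characters, making detokenization exact. Tokenization is
idempotent on its own output surfaces.

Linguistic layers follow a total order (tokenization < POS < lemmatization
< chunking < dependency) and are filled lazily: a pipeline requests only
the deepest level some component needs, and a dictionary-only pipeline
stops at tokenization. The default provider is a deterministic passthrough
stub (lowercased surface as lemma, constant POS tag); real taggers attach
through the `LinguisticProvider` contract.

## Dictionary matching

Surfaces are case-folded by simple lowercasing (no Unicode normalization
beyond what the input already has; a length-preserving per-character fold
guards offsets against the few locale oddities). Each dictionary compiles
to its own Aho–Corasick automaton — built in-package, as the matching
primitive is central to the tool — giving linear-time scans with no
dependence on dictionary size.

The matching directives, in order:

1. candidates must start at a token start and end at a token end (an
   unconstrained character automaton would find "rat" inside "strata");
2. within one dictionary, candidates contained in a larger candidate are
   dropped (largest span wins), and remaining same-dictionary partial
   overlaps resolve leftmost-first, then longest;
3. stopword surfaces are dropped;
4. surfaces shorter than `min_length` characters (default 3, counting
   internal spaces and hyphens) are dropped — short acronyms are recovered
   later by abbreviation resolution rather than risked as matches;
5. survivors from all dictionaries enter the tree; equal spans merge
   identifiers in dictionary-priority order.

Filters 3–4 apply to dictionary matching only; mentions from NER providers
and abbreviation propagation are exempt (they carry their own evidence).
Approximate matching is deliberately not offered — orthographic variants
belong in the dictionary as extra names.

## Normalization

`normalize_mention` queries dictionaries in priority order. Within a
dictionary the winning surface is the longest token-aligned sub-span of the
mention whose folded text is an entry (character length, leftmost on ties);
all identifiers of that surface are returned and the search stops. The full
mention is always the longest candidate, so "exact before partial" needs no
separate rule. Extra tokens are tolerated only on the mention side: a
dictionary entry longer than the mention never matches. Mentions that no
dictionary resolves are kept or discarded by policy (`keep_unmatched`).

A species-consistency post-hook for gene identifiers (drop identifiers of
species never mentioned in the document) would require per-identifier
species metadata beyond the identifier quadruple and is out of scope.

## Abbreviation resolution

The definition detector follows the classic short-form/long-form
pattern-matching recipe. Codified thresholds (config constants): the
parenthesized short form has at most 2 words and 2–10 characters, at least
one letter, and an alphanumeric first character; the long-form window holds
up to `min(|SF| + 5, 2·|SF|)` words before the parenthesis; a window suffix
is valid when every SF character occurs in it in order (case-insensitive)
and SF's first character starts one of its words; the shortest valid suffix
wins. When exactly one of the two forms coincides with an existing
annotation, the counterpart is added with the same identifiers, and every
later occurrence of the newly annotated surface in the same document is
annotated too — case-sensitively for short forms (acronym case is
meaningful), case-insensitively for long forms.

## Disambiguation strategies

* **By depth** — drop nodes deeper than a limit (subtrees wholesale).
* **Nested same group** — drop any node with a proper ancestor sharing at
  least one semantic group. *Any* ancestor counts, not just the parent:
  PRGE ⊃ DISO ⊃ PRGE removes the innermost node.
* **By priority** — while two nodes nest or intersect, remove the one whose
  best group ranks lower in a user list (ties: keep the larger span, then
  the leftmost). The scan is pre-order with restart after each removal,
  which makes the procedure deterministic and terminating; the result is a
  flat antichain of disjoint annotations.

All three are idempotent and never alter the spans or identifiers of
surviving nodes.

## Formats

* **A1**: one `T` line per node (pre-order, document-absolute offsets,
  first group for multi-group nodes), identifiers on `AnnotatorNotes`
  lines — the standard extension point for information the `T` line cannot
  carry. `read_a1` inverts `write_a1` exactly.
* **CoNLL**: one token per line with one BIO column per tree depth present,
  so nested and intersected annotations survive; only semantic groups fit
  the format. Same-depth collisions on a token keep the pre-order-first
  annotation.
* **Inline XML**: `<e id="...">` elements, at most two nesting levels;
  deeper nodes and crossing siblings (which cannot be serialized as
  well-formed XML) are dropped with a logged warning. When the input was
  XML, annotations are re-embedded into the original document with every
  non-ROI byte preserved exactly, via the per-character offset map the XML
  reader maintains (entities map several-to-one).
* **JSON** and the **indented tree format** mirror the full tree, including
  all identifiers.

The XML reader selects user-named tags as regions of interest; nested
occurrences of a selected tag count once (outermost wins). Well-formedness
is validated with `lxml`; the offset-tracking scan is done in-package
because the DOM does not expose source offsets.

## Pipeline, context, batch

A pipeline is a FIFO module list — reader first, writer last — with tagger
/ loader / hybrid kinds in between. The `Context` loads resources lazily
and records what was touched (`loaded_resources`), so a dictionary-only
pipeline demonstrably never initializes an NER provider. Batch processing
distributes files over a thread pool; automata and dictionaries are shared
read-only, providers flagged non-shareable are duplicated per worker.
Files are independent, so outputs are byte-identical for any worker count.
The core pipeline has no randomness; a stochastic provider must expose its
own seed. The CLI exposes the whole surface as `biocr annotate / evaluate
/ fixtures` subcommands with exit codes 0 (ok), 1 (some files failed),
2 (bad invocation).

## Evaluation

Span strategies form a lattice (exact ⇒ left/right ⇒ shared ⇒ overlap);
identifier strategies: *exact* requires the predicted identifier list to
equal the gold list (for a single gold identifier: exactly one prediction,
and it matches), *contains* requires the gold identifiers to be among the
predictions. Matching is one-to-one and greedy: golds in document order,
each taking the accepting unmatched prediction with the smallest start,
largest span on ties — a stated convention, since several pairings are
defensible when acceptance is relaxed. Predictions and golds are compared
within the same semantic group. Counts are pooled over documents before
computing P/R/F1; zero denominators resolve to 0.

## Synthetic fixtures

The generator emulates the structural properties the pipeline must handle —
prioritized dictionaries, ambiguous surfaces (default rate 0.2), nested
mentions that cross dictionaries (0.25), abbreviation definitions with
derivable short forms (0.25), multi-document corpora (8 documents × 6
sentences, 40 concepts) — with pronounceable names over a carrier
vocabulary disjoint from every generated name. Each concept uses fresh
words (deliberate nesting excepted), so the planted annotations are
provably the complete match set and the gold is exact by construction.
Defaults were chosen once as a plausible density of mentions per sentence
for abstract-like text; generation is bit-reproducible per seed.

What the fixtures do **not** emulate: real name statistics (length,
punctuation-heavy gene symbols, Greek letters), boundary ambiguity between
overlapping real lexicons, noisy OCR text, or corpus-scale dictionaries.
A perfect score on fixtures therefore validates the machinery — offsets,
priority logic, tree consistency, format round-trips — not recognition
quality on real corpora, which depends on the dictionaries and models
supplied.

## Numerical and degenerate-input choices

Empty documents yield empty but valid output in every format. Zero-length
ROI regions are legal. Duplicate (surface, identifier) dictionary pairs are
de-duplicated; identical surfaces accumulate identifiers across lines and
files. Malformed dictionaries, identifiers, A1 lines and XML all fail with
located errors rather than silent skips; a failing document in a batch is
recorded in the summary and does not abort the run.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
1000 random sentence/dictionary fixtures for the matcher-oracle
equivalence, exhaustive permutations of up to 5 spans for tree-order
invariance, 8-document corpora for end-to-end closure, worker counts 1–8
for batch determinism. These sizes exercise every code path while keeping
the whole suite around two seconds.

## Known limitations

Annotations never cross sentence boundaries and spans are contiguous.
CRF training/inference is not implemented — statistical NER attaches via
the provider contract (the built-in reference provider is gazetteer-backed).
Inline XML output cannot represent more than two nesting levels or crossing
annotations. The CoNLL reader direction is not implemented (the format is
lossy with respect to identifiers).
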