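# biocr

Modular biomedical concept recognition: find mentions of biomedical concepts
(genes/proteins, disorders, species, anatomy, chemicals, ...) in text,
normalize them to identifiers from curated resources, keep every nested and
intersected reading in a per-sentence **concept tree**, and write the
standard annotation formats.

## Who this is for

Text-mining practitioners who need to annotate document collections with
heterogeneous biomedical concepts — from curated dictionaries, from pluggable
statistical NER providers, or both — without wiring half a dozen tools
together. The package is both a library (every stage is an importable
function over a shared corpus model) and a command-line tool (`biocr`).

## The method

**Dictionary matching.** Concept dictionaries are TSV files
(`source:id:type:group<TAB>name1|name2|...`) collected in a folder with a
priority file that fixes their order. All surfaces of a dictionary are
compiled into an Aho–Corasick automaton, so matching a sentence is linear in
its length regardless of dictionary size. Matching is case-insensitive and
exact; candidates must align with token boundaries; within one dictionary
only the entry with the largest span survives; a stopword list and a
minimum surface length (3 characters) filter out non-informative hits.

**Concept tree.** Every sentence keeps its annotations in a hierarchy:
a mention nested inside a longer mention becomes its child, intersecting
mentions coexist as siblings, and equal spans merge their identifier lists
(that is how ambiguity such as `NF1`-the-disease vs `NF1`-the-gene is
represented). Insertion order never changes the resulting tree.

**Normalization.** Mentions found by an NER provider gain identifiers by
querying the dictionaries in priority order: the first dictionary with a
match supplies its identifiers and the search stops, so preferred names
(first dictionary) beat synonyms (later ones). A surface covering only a
sub-span of the mention is accepted for the whole mention (`BRCA1` resolves
`BRCA1 gene`), but extra tokens on the dictionary side never match.

**Post-processing.** Abbreviation definitions (`long form (SF)`) are
detected by pattern rules; when one form is annotated, the other — and every
later occurrence of it in the document — inherits its identifiers. Three
disambiguation strategies prune the tree: by depth, by removing concepts
nested inside a larger concept of the same semantic group, or by a
prioritized group list that flattens the tree to disjoint annotations.

**Evaluation.** The harness scores predictions against gold standoff with
five span strategies (exact / left / right / shared / overlap) and two
identifier strategies (exact / contains), micro-averaging TP/FP/FN over all
documents:

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2·P·R / (P + R)

## Worked example

```python
from biocr import Context, build_pipeline, run_pipeline, DictionaryGroup, Dictionary
from biocr.core import parse_identifier

species = Dictionary(name="species")
species.add("rat", parse_identifier("NCBI:10114:species:SPEC"))
ctx = Context(dictionary_group=DictionaryGroup([species]))

corpus, a1 = run_pipeline(build_pipeline(), ctx, "The rat was examined.")
print(a1, end="")
```

prints

```
T1	SPEC 4 7	rat
#1	AnnotatorNotes T1	NCBI:10114:species:SPEC
```

i.e. one annotation over characters 4–7 ("rat"), semantic group SPEC,
normalized to the NCBI Taxonomy genus *Rattus* (identifier 10114), in brat
A1 standoff with the identifier on an AnnotatorNotes line.

From the shell, the equivalent batch run over a folder of Pubmed-style XML:

```bash
biocr annotate -i input/ -if XML -o output/ -of XML \
    -x AbstractText,ArticleTitle -d resources/dictionaries/ -t 6
biocr evaluate --pred output/ --gold gold/ --span exact --ids exact
biocr fixtures --seed 1 --out fixtures/     # synthetic dictionaries + gold
```

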