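"""Pipeline assembly and execution, resource context, batch processing.

A pipeline is a FIFO list of modules: a reader first, a writer last, and any
number of processing modules in between.  Modules come in five kinds —
reader, tagger (text to text), loader (text to memory), hybrid (both) and
writer — and each document flows through them sequentially.

The :class:`Context` owns every heavyweight resource (dictionary automata,
NER providers, linguistic providers, the sentence splitter) and loads each
one lazily, the first time a pipeline actually needs it: a dictionary-only
run never initializes an NER provider.  Read-only resources are shared
across concurrent workers; providers that are not thread-safe are duplicated
per worker from their factory.
"""

from __future__ import annotations

import enum
import fnmatch
import gzip
import io
import logging
import os
import threading
import zipfile
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .core import Corpus, Sentence
from .io_formats import (
    RoiDocument,
    read_raw,
    read_xml,
    write_a1,
    write_conll,
    write_inline_xml,
    write_json,
    write_neji,
)
from .lexicon import DictionaryGroup, Matcher, load_group, match_sentence
from .ner import NerProvider, NormalizationPolicy, apply_normalization, recognize
from .nlp import (
    LinguisticProvider,
    ParsingLevel,
    PassthroughProvider,
    annotate_layers,
    split_sentences,
    tokenize,
)
from .postprocess import extend_by_abbreviations, filter_by_priority, prune_by_depth, remove_nested_same_group

logger = logging.getLogger(__name__)


class ModuleKind(enum.Enum):
    READER = "READER"
    TAGGER = "TAGGER"
    LOADER = "LOADER"
    HYBRID = "HYBRID"
    WRITER = "WRITER"


@dataclass
class PipelineState:
    """What flows between modules: the raw input, the ROI view, the corpus
    under construction and, at the end, the serialized output."""

    doc_id: str
    raw: str
    roi_doc: Optional[RoiDocument] = None
    corpus: Optional[Corpus] = None
    output: Optional[str] = None


@dataclass
class PipelineModule:
    kind: ModuleKind
    name: str
    run: Callable[[PipelineState, "Context"], None]


class PipelineError(RuntimeError):
    pass


@dataclass
class Pipeline:
    """FIFO module list; must start with a reader and end with a writer."""

    modules: List[PipelineModule]

    def __post_init__(self) -> None:
        if not self.modules:
            raise PipelineError("pipeline is empty")
        if self.modules[0].kind is not ModuleKind.READER:
            raise PipelineError("pipeline must start with a READER module")
        if self.modules[-1].kind is not ModuleKind.WRITER:
            raise PipelineError("pipeline must end with a WRITER module")

    @property
    def ner_provider_names(self) -> List[str]:
        names: List[str] = []
        for m in self.modules:
            names.extend(getattr(m.run, "ner_providers", []))
        return names

    @property
    def parsing_override(self) -> Optional[ParsingLevel]:
        for m in self.modules:
            override = getattr(m.run, "parsing_override", None)
            if override is not None:
                return override
        return None


class Context:
    """Lazily loaded, shareable resource container.

    Resources are declared as factories and materialized on first access;
    ``loaded_resources`` exposes which ones a run actually touched.  A
    worker-local view (:meth:`for_worker`) shares every read-only resource
    and duplicates providers whose ``shareable`` flag is False.
    """

    def __init__(
        self,
        dictionary_group: Optional[DictionaryGroup] = None,
        dictionaries_folder: Optional[str] = None,
        ner_provider_factories: Optional[Dict[str, Callable[[], NerProvider]]] = None,
        linguistic_provider: Optional[LinguisticProvider] = None,
        splitter: Callable[[str], List[Tuple[int, int]]] = split_sentences,
        keep_unmatched: bool = False,
        stopwords: frozenset = frozenset(),
    ):
        self._group = dictionary_group
        self._folder = dictionaries_folder
        self._stopwords = stopwords
        self._matcher: Optional[Matcher] = None
        self._ner_factories = dict(ner_provider_factories or {})
        self._ner_instances: Dict[str, NerProvider] = {}
        self.linguistic_provider = linguistic_provider or PassthroughProvider()
        self.splitter = splitter
        self.keep_unmatched = keep_unmatched
        self.loaded_resources: set = set()
        self._lock = threading.Lock()

    @property
    def dictionary_group(self) -> DictionaryGroup:
        with self._lock:
            if self._group is None:
                if self._folder is None:
                    raise PipelineError("no dictionaries configured")
                self._group = load_group(self._folder, stopwords=self._stopwords)
                self.loaded_resources.add("dictionary_group")
            else:
                self.loaded_resources.add("dictionary_group")
            return self._group

    @property
    def matcher(self) -> Matcher:
        group = self.dictionary_group
        with self._lock:
            if self._matcher is None:
                self._matcher = Matcher(group)
                self.loaded_resources.add("matcher")
            return self._matcher

    def ner_provider(self, name: str) -> NerProvider:
        with self._lock:
            if name not in self._ner_instances:
                if name not in self._ner_factories:
                    raise PipelineError(f"unknown NER provider: {name}")
                self._ner_instances[name] = self._ner_factories[name]()
                self.loaded_resources.add(f"ner:{name}")
            return self._ner_instances[name]

    def ner_required_level(self, names: Sequence[str]) -> ParsingLevel:
        level = ParsingLevel.TOKENIZATION
        for n in names:
            level = max(level, self.ner_provider(n).required_level)
        return level

    def for_worker(self) -> "Context":
        """Worker-local view: shared read-only resources, duplicated
        non-shareable providers."""
        clone = Context(
            dictionary_group=self._group,
            dictionaries_folder=self._folder,
            ner_provider_factories=self._ner_factories,
            linguistic_provider=(
                self.linguistic_provider
                if self.linguistic_provider.shareable
                else type(self.linguistic_provider)()
            ),
            splitter=self.splitter,
            keep_unmatched=self.keep_unmatched,
            stopwords=self._stopwords,
        )
        clone._matcher = self._matcher  # automata are read-only, safe to share
        for name, inst in self._ner_instances.items():
            if inst.shareable:
                clone._ner_instances[name] = inst
        return clone


def resolve_parsing_level(
    context: Context,
    pipeline: Pipeline,
    override: Optional[ParsingLevel] = None,
) -> ParsingLevel:
    """Deepest linguistic level the pipeline needs.

    Tokenization when only dictionary matching is present, the maximum
    required level over the pipeline's NER providers otherwise; an explicit
    user override wins.
    """
    if override is not None:
        return override
    pipeline_override = pipeline.parsing_override
    if pipeline_override is not None:
        return pipeline_override
    names = pipeline.ner_provider_names
    if not names:
        return ParsingLevel.TOKENIZATION
    return context.ner_required_level(names)


# -- built-in module factories ------------------------------------------------


def reader_module(input_format: str = "RAW", xml_tags: Sequence[str] = ()) -> PipelineModule:
    fmt = input_format.upper()
    if fmt not in {"RAW", "XML"}:
        raise PipelineError(f"unknown input format: {input_format}")
    if fmt == "XML" and not xml_tags:
        raise PipelineError("XML input requires at least one tag of interest")

    def run(state: PipelineState, context: Context) -> None:
        state.roi_doc = read_xml(state.raw, xml_tags) if fmt == "XML" else read_raw(state.raw)

    return PipelineModule(ModuleKind.READER, f"reader:{fmt.lower()}", run)


def sentence_module() -> PipelineModule:
    def run(state: PipelineState, context: Context) -> None:
        doc = state.roi_doc
        text = doc.text
        sentences: List[Sentence] = []
        roi_spans = doc.roi_spans()
        sid = 0
        for roi_start, roi_end in roi_spans:
            for s, e in context.splitter(text[roi_start:roi_end]):
                seg = text[roi_start + s: roi_start + e]
                sentences.append(
                    Sentence(sid=sid, start=roi_start + s, end=roi_start + e,
                             text=seg, tokens=tokenize(seg))
                )
                sid += 1
        state.corpus = Corpus(
            doc_id=state.doc_id, text=text, sentences=sentences,
            roi_map=roi_spans, source=doc,
        )

    return PipelineModule(ModuleKind.HYBRID, "sentences", run)


def nlp_module(level: Optional[ParsingLevel] = None) -> PipelineModule:
    def run(state: PipelineState, context: Context) -> None:
        target = level if level is not None else ParsingLevel.TOKENIZATION
        for sentence in state.corpus.sentences:
            annotate_layers(sentence, context.linguistic_provider, target)

    run.parsing_override = level  # type: ignore[attr-defined]
    return PipelineModule(ModuleKind.LOADER, "nlp", run)


def dictionary_module() -> PipelineModule:
    def run(state: PipelineState, context: Context) -> None:
        matcher = context.matcher
        for sentence in state.corpus.sentences:
            match_sentence(sentence, context.dictionary_group, matcher)

    return PipelineModule(ModuleKind.LOADER, "dictionary-matcher", run)


def ner_module(provider_names: Sequence[str]) -> PipelineModule:
    names = list(provider_names)

    def run(state: PipelineState, context: Context) -> None:
        policy = NormalizationPolicy(
            group=context.dictionary_group, keep_unmatched=context.keep_unmatched
        )
        for sentence in state.corpus.sentences:
            for name in names:
                provider = context.ner_provider(name)
                mentions = recognize(sentence, provider)
                apply_normalization(sentence, mentions, policy)

    run.ner_providers = names  # type: ignore[attr-defined]
    return PipelineModule(ModuleKind.LOADER, "ner", run)


def abbreviation_module() -> PipelineModule:
    def run(state: PipelineState, context: Context) -> None:
        extend_by_abbreviations(state.corpus)

    return PipelineModule(ModuleKind.LOADER, "abbreviations", run)


def disambiguation_module(
    strategy: str = "none",
    depth: int = 1,
    priority_list: Sequence[str] = (),
) -> PipelineModule:
    def run(state: PipelineState, context: Context) -> None:
        for sentence in state.corpus.sentences:
            if strategy == "depth":
                prune_by_depth(sentence.tree, depth)
            elif strategy == "same_group":
                remove_nested_same_group(sentence.tree)
            elif strategy == "priority":
                filter_by_priority(sentence.tree, priority_list)
            elif strategy != "none":
                raise PipelineError(f"unknown disambiguation strategy: {strategy}")

    return PipelineModule(ModuleKind.LOADER, f"disambiguation:{strategy}", run)


_WRITERS = {
    "A1": write_a1,
    "CONLL": write_conll,
    "XML": write_inline_xml,
    "JSON": write_json,
    "NEJI": write_neji,
}

OUTPUT_EXTENSIONS = {"A1": "a1", "CONLL": "conll", "XML": "xml", "JSON": "json", "NEJI": "neji"}


def writer_module(output_format: str = "A1") -> PipelineModule:
    fmt = output_format.upper()
    if fmt not in _WRITERS:
        raise PipelineError(f"unknown output format: {output_format}")

    def run(state: PipelineState, context: Context) -> None:
        buf = io.StringIO()
        _WRITERS[fmt](state.corpus, buf)
        state.output = buf.getvalue()

    return PipelineModule(ModuleKind.WRITER, f"writer:{fmt.lower()}", run)


def build_pipeline(
    input_format: str = "RAW",
    output_format: str = "A1",
    xml_tags: Sequence[str] = (),
    use_dictionaries: bool = True,
    ner_providers: Sequence[str] = (),
    abbreviations: bool = True,
    disambiguation: str = "none",
    disambiguation_depth: int = 1,
    disambiguation_priority: Sequence[str] = (),
    parsing_level: Optional[ParsingLevel] = None,
) -> Pipeline:
    """Assemble the standard annotation pipeline."""
    modules = [reader_module(input_format, xml_tags), sentence_module()]
    modules.append(nlp_module(parsing_level))
    if use_dictionaries:
        modules.append(dictionary_module())
    if ner_providers:
        modules.append(ner_module(ner_providers))
    if abbreviations:
        modules.append(abbreviation_module())
    if disambiguation != "none":
        modules.append(
            disambiguation_module(disambiguation, disambiguation_depth, disambiguation_priority)
        )
    modules.append(writer_module(output_format))
    return Pipeline(modules)


def run_pipeline(
    pipeline: Pipeline,
    context: Context,
    document: str,
    doc_id: str = "doc",
) -> Tuple[Corpus, str]:
    """Execute the pipeline on one document; deterministic for a fixed
    input and configuration.  Returns the corpus and the serialized output."""
    # resolve the parsing level up front so the nlp module is never deeper
    # than required (lazy resolution)
    level = resolve_parsing_level(context, pipeline)
    state = PipelineState(doc_id=doc_id, raw=document)
    for module in pipeline.modules:
        if module.name == "nlp" and getattr(module.run, "parsing_override", None) is None:
            annotated = nlp_module(level)
            annotated.run(state, context)
            continue
        module.run(state, context)
    return state.corpus, state.output


# -- batch processing ---------------------------------------------------------


@dataclass
class BatchJob:
    input_folder: str
    output_folder: str
    input_format: str = "RAW"
    output_format: str = "A1"
    xml_tags: Sequence[str] = ()
    wildcard: str = "*"
    workers: int = 1
    compressed: bool = False
    pipeline_factory: Optional[Callable[[], Pipeline]] = None

    def make_pipeline(self) -> Pipeline:
        if self.pipeline_factory is not None:
            return self.pipeline_factory()
        return build_pipeline(
            input_format=self.input_format,
            output_format=self.output_format,
            xml_tags=self.xml_tags,
        )


@dataclass
class BatchSummary:
    processed: List[str] = field(default_factory=list)
    failed: Dict[str, str] = field(default_factory=dict)
    n_annotations: int = 0

    @property
    def ok(self) -> bool:
        return not self.failed


def _read_input_file(path: str) -> str:
    if path.endswith(".gz"):
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            return fh.read()
    if path.endswith(".zip"):
        with zipfile.ZipFile(path) as zf:
            names = zf.namelist()
            if not names:
                return ""
            return zf.read(names[0]).decode("utf-8")
    with open(path, encoding="utf-8") as fh:
        return fh.read()


def _strip_compression_suffix(name: str) -> str:
    for suffix in (".gz", ".zip"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def run_batch(job: BatchJob, context: Context) -> BatchSummary:
    """Process every matching file in the input folder.

    Each file is independent, so the result set is identical to sequential
    execution regardless of the worker count; an unreadable file is recorded
    in the summary without affecting the others.
    """
    if job.workers < 1:
        raise ValueError("worker count must be >= 1")
    if not os.path.isdir(job.input_folder):
        raise FileNotFoundError(f"input folder not found: {job.input_folder}")
    os.makedirs(job.output_folder, exist_ok=True)
    files = sorted(
        f
        for f in os.listdir(job.input_folder)
        if os.path.isfile(os.path.join(job.input_folder, f))
        and fnmatch.fnmatch(_strip_compression_suffix(f), job.wildcard)
    )
    summary = BatchSummary()
    ext = OUTPUT_EXTENSIONS[job.output_format.upper()]
    lock = threading.Lock()
    local = threading.local()

    def worker_context() -> Context:
        if not hasattr(local, "ctx"):
            local.ctx = context.for_worker() if job.workers > 1 else context
        return local.ctx

    def process(fname: str) -> None:
        path = os.path.join(job.input_folder, fname)
        try:
            raw = _read_input_file(path)
            pipeline = job.make_pipeline()
            corpus, output = run_pipeline(pipeline, worker_context(), raw, doc_id=fname)
            stem = os.path.splitext(_strip_compression_suffix(fname))[0]
            out_path = os.path.join(job.output_folder, f"{stem}.{ext}")
            if os.path.exists(out_path):
                logger.warning("overwriting existing output %s", out_path)
            with open(out_path, "w", encoding="utf-8") as fh:
                fh.write(output)
            with lock:
                summary.processed.append(fname)
                summary.n_annotations += corpus.n_annotations()
        except Exception as exc:  # noqa: BLE001 - batch must survive bad files
            logger.error("failed to process %s: %s", fname, exc)
            with lock:
                summary.failed[fname] = str(exc)

    if job.workers == 1:
        for f in files:
            process(f)
    else:
        with ThreadPoolExecutor(max_workers=job.workers) as pool:
            list(pool.map(process, files))
    summary.processed.sort()
    return summary
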