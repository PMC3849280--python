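"""Pipeline assembly, lazy resource context, batch processing and the CLI."""

import gzip
import os

import pytest
from click.testing import CliRunner

from biocr.cli import main
from biocr.core import Identifier
from biocr.engine import (
    BatchJob,
    Context,
    Pipeline,
    PipelineError,
    build_pipeline,
    dictionary_module,
    reader_module,
    resolve_parsing_level,
    run_batch,
    run_pipeline,
    sentence_module,
    writer_module,
)
from biocr.fixtures import FixtureSpec, build_fixture_set, gen_gold_corpus, write_fixture_files
from biocr.lexicon import DictionaryGroup
from biocr.ner import GazetteerNerProvider
from biocr.nlp import ParsingLevel

from conftest import ident, make_dictionary


def species_group():
    return DictionaryGroup(
        [make_dictionary("species", {"rat": [Identifier("NCBI", "10114", "species", "SPEC")]})]
    )


class TestPipelineAssembly:
    def test_reader_first_writer_last_enforced(self):
        with pytest.raises(PipelineError):
            Pipeline([sentence_module(), writer_module()])
        with pytest.raises(PipelineError):
            Pipeline([reader_module(), dictionary_module()])
        Pipeline([reader_module(), sentence_module(), writer_module()])

    def test_unknown_formats_rejected(self):
        with pytest.raises(PipelineError):
            reader_module("PDF")
        with pytest.raises(PipelineError):
            writer_module("YAML")


class TestResolveParsingLevel:
    def test_dictionary_only_is_tokenization(self):
        pipeline = build_pipeline()
        assert resolve_parsing_level(Context(dictionary_group=species_group()),
                                     pipeline) == ParsingLevel.TOKENIZATION

    def test_provider_requirement_wins(self):
        ctx = Context(
            dictionary_group=species_group(),
            ner_provider_factories={
                "g": lambda: GazetteerNerProvider(
                    {"rat": "SPEC"}, required_level=ParsingLevel.LEMMATIZATION
                )
            },
        )
        pipeline = build_pipeline(ner_providers=["g"])
        assert resolve_parsing_level(ctx, pipeline) == ParsingLevel.LEMMATIZATION

    def test_explicit_override(self):
        ctx = Context(dictionary_group=species_group())
        pipeline = build_pipeline()
        assert resolve_parsing_level(ctx, pipeline,
                                     ParsingLevel.DEPENDENCY) == ParsingLevel.DEPENDENCY


class TestRunPipeline:
    def test_annotates_and_writes_a1(self):
        ctx = Context(dictionary_group=species_group())
        corpus, output = run_pipeline(build_pipeline(), ctx, "The rat was examined.")
        assert corpus.n_annotations() == 1
        assert output.startswith("T1\tSPEC 4 7\trat\n")

    def test_empty_document(self):
        ctx = Context(dictionary_group=species_group())
        corpus, output = run_pipeline(build_pipeline(), ctx, "")
        assert corpus.sentences == [] and output == ""

    def test_deterministic(self):
        ctx = Context(dictionary_group=species_group())
        doc = "The rat was examined. The rat recovered."
        out1 = run_pipeline(build_pipeline(), ctx, doc)[1]
        out2 = run_pipeline(build_pipeline(), ctx, doc)[1]
        assert out1 == out2

    def test_xml_pipeline(self):
        ctx = Context(dictionary_group=species_group())
        xml = "<d><ArticleTitle>A rat study.</ArticleTitle><junk>rat</junk></d>"
        pipeline = build_pipeline(input_format="XML", output_format="XML",
                                  xml_tags=("ArticleTitle",))
        corpus, output = run_pipeline(pipeline, ctx, xml)
        assert corpus.n_annotations() == 1  # the <junk> rat is outside the ROI
        assert "<junk>rat</junk>" in output

    def test_fixture_gold_reproduced(self):
        spec = FixtureSpec(seed=3, n_docs=2)
        fx = build_fixture_set(spec)
        docs = gen_gold_corpus(spec, fx)
        ctx = Context(dictionary_group=fx.group)
        for doc in docs:
            corpus, _ = run_pipeline(build_pipeline(), ctx, doc.text, doc.doc_id)
            got = {
                (s.start + a.start, s.start + a.end,
                 frozenset(str(i) for i in a.ids))
                for s, a in corpus.annotations()
            }
            expected = {
                (u.start, u.end, frozenset(str(i) for i in u.ids)) for u in doc.gold
            }
            assert got == expected

    def test_lazy_loading_dictionary_only(self):
        ctx = Context(
            dictionary_group=species_group(),
            ner_provider_factories={"g": lambda: GazetteerNerProvider({"rat": "SPEC"})},
        )
        run_pipeline(build_pipeline(), ctx, "The rat was examined.")
        assert not any(r.startswith("ner:") for r in ctx.loaded_resources)
        assert "matcher" in ctx.loaded_resources


class TestRunBatch:
    def _populate(self, folder, n=10):
        os.makedirs(folder, exist_ok=True)
        for i in range(n):
            with open(os.path.join(folder, f"doc{i}.txt"), "w") as fh:
                fh.write(f"The rat was examined in run {i}. Another rat appeared.")

    def test_workers_equivalent(self, tmp_path):
        inp = tmp_path / "in"
        self._populate(str(inp))
        ctx = Context(dictionary_group=species_group())
        outputs = {}
        for workers in (1, 2, 4, 8):
            out = tmp_path / f"out{workers}"
            job = BatchJob(input_folder=str(inp), output_folder=str(out),
                           wildcard="*.txt", workers=workers)
            summary = run_batch(job, ctx)
            assert summary.ok and len(summary.processed) == 10
            outputs[workers] = {
                f: (out / f).read_bytes() for f in os.listdir(out)
            }
        assert outputs[1] == outputs[2] == outputs[4] == outputs[8]

    def test_wildcard_filter(self, tmp_path):
        inp = tmp_path / "in"
        os.makedirs(inp)
        (inp / "a.xml").write_text("<d><t>rat</t></d>")
        (inp / "notes.txt").write_text("The rat was examined.")
        ctx = Context(dictionary_group=species_group())
        job = BatchJob(input_folder=str(inp), output_folder=str(tmp_path / "out"),
                       input_format="XML", xml_tags=("t",), wildcard="*.xml")
        summary = run_batch(job, ctx)
        assert summary.processed == ["a.xml"]

    def test_empty_folder(self, tmp_path):
        inp = tmp_path / "in"
        os.makedirs(inp)
        summary = run_batch(
            BatchJob(input_folder=str(inp), output_folder=str(tmp_path / "out")),
            Context(dictionary_group=species_group()),
        )
        assert summary.processed == [] and summary.ok

    def test_bad_file_recorded_others_survive(self, tmp_path):
        inp = tmp_path / "in"
        os.makedirs(inp)
        (inp / "good.xml").write_text("<d><t>rat</t></d>")
        (inp / "bad.xml").write_text("<d><t>rat</d>")
        ctx = Context(dictionary_group=species_group())
        job = BatchJob(input_folder=str(inp), output_folder=str(tmp_path / "out"),
                       input_format="XML", xml_tags=("t",), wildcard="*.xml")
        summary = run_batch(job, ctx)
        assert summary.processed == ["good.xml"]
        assert "bad.xml" in summary.failed

    def test_gzip_input(self, tmp_path):
        inp = tmp_path / "in"
        os.makedirs(inp)
        with gzip.open(inp / "doc.txt.gz", "wt") as fh:
            fh.write("The rat was examined.")
        ctx = Context(dictionary_group=species_group())
        job = BatchJob(input_folder=str(inp), output_folder=str(tmp_path / "out"),
                       wildcard="*.txt", compressed=True)
        summary = run_batch(job, ctx)
        assert summary.processed == ["doc.txt.gz"]
        assert (tmp_path / "out" / "doc.a1").exists()

    def test_invalid_worker_count(self, tmp_path):
        with pytest.raises(ValueError):
            run_batch(BatchJob(input_folder=str(tmp_path), output_folder=str(tmp_path),
                               workers=0),
                      Context(dictionary_group=species_group()))


class TestCli:
    def _dict_folder(self, tmp_path):
        d = tmp_path / "dicts"
        os.makedirs(d)
        (d / "species.tsv").write_text("NCBI:10114:species:SPEC\trat|rats\n")
        (d / "priority").write_text("species.tsv\n")
        return str(d)

    def test_no_arguments_shows_usage_nonzero(self):
        result = CliRunner().invoke(main, [])
        assert result.exit_code != 0
        assert "Usage" in result.output

    def test_full_invocation(self, tmp_path):
        inp = tmp_path / "in"
        os.makedirs(inp)
        (inp / "a.xml").write_text(
            "<d><ArticleTitle>A rat study.</ArticleTitle>"
            "<AbstractText>The rat recovered.</AbstractText></d>"
        )
        result = CliRunner().invoke(main, [
            "annotate", "-i", str(inp), "-if", "XML", "-o", str(tmp_path / "out"),
            "-of", "XML", "-x", "AbstractText,ArticleTitle",
            "-d", self._dict_folder(tmp_path), "-t", "6",
        ])
        assert result.exit_code == 0, result.output
        assert "processed 1 file(s)" in result.output
        assert (tmp_path / "out" / "a.xml").exists()

    def test_threads_zero_rejected(self, tmp_path):
        inp = tmp_path / "in"
        os.makedirs(inp)
        result = CliRunner().invoke(main, [
            "annotate", "-i", str(inp), "-o", str(tmp_path / "out"),
            "-d", self._dict_folder(tmp_path), "-t", "0",
        ])
        assert result.exit_code == 2

    def test_xml_tags_require_xml_input(self, tmp_path):
        inp = tmp_path / "in"
        os.makedirs(inp)
        result = CliRunner().invoke(main, [
            "annotate", "-i", str(inp), "-o", str(tmp_path / "out"),
            "-d", self._dict_folder(tmp_path), "-x", "ArticleTitle",
        ])
        assert result.exit_code == 2

    def test_missing_mandatory_flags(self):
        result = CliRunner().invoke(main, ["annotate"])
        assert result.exit_code == 2
        assert "Usage" in result.output or "Missing" in result.output

    def test_evaluate_subcommand(self, tmp_path):
        pred = tmp_path / "pred"
        gold = tmp_path / "gold"
        os.makedirs(pred)
        os.makedirs(gold)
        (gold / "d.a1").write_text("T1\tSPEC 4 7\trat\n")
        (pred / "d.a1").write_text("T1\tSPEC 4 7\trat\nT2\tSPEC 9 12\trat\n")
        result = CliRunner().invoke(main, [
            "evaluate", "--pred", str(pred), "--gold", str(gold), "--span", "exact",
        ])
        assert result.exit_code == 0
        overall = [l for l in result.output.splitlines() if l.startswith("overall")][0]
        assert overall.split("\t")[1:4] == ["1", "1", "0"]

    def test_fixtures_subcommand(self, tmp_path):
        result = CliRunner().invoke(main, [
            "fixtures", "--seed", "7", "--out", str(tmp_path / "fx"),
            "--docs", "2", "--sentences", "3",
        ])
        assert result.exit_code == 0
        assert (tmp_path / "fx" / "dictionaries" / "priority").exists()
        assert len(list((tmp_path / "fx" / "docs").iterdir())) == 2
        assert len(list((tmp_path / "fx" / "gold").iterdir())) == 2
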