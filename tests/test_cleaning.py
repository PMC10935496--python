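"""Line cleaning, assembly, corpus building and audit conservation."""

import re

import numpy as np
import pytest

from pathcorpus.blocks import TextType
from pathcorpus.cases import SelectionOutcome
from pathcorpus.cleaning import (
    AuditLog,
    CleaningConfig,
    ConfigError,
    CorpusRecord,
    NEEDS_REVIEW,
    SHORT_REPORT,
    assemble_text,
    build_corpus,
    clean_document,
    example_cleaning_regexes,
    flag_short_reports,
    read_corpus_jsonl,
    remove_handwritten_lines,
    remove_matched_lines,
    summarize_corpus,
    write_corpus_jsonl,
)
from pathcorpus.simulate import GenSpec, PlantRates, generate_labeled_corpus

from conftest import make_doc, make_line, make_page


class TestHandwritingRemoval:
    def test_all_handwritten_removed_mixed_kept(self):
        hw = make_line("x y z", top=0.1, line_id="hw",
                       text_type=TextType.HANDWRITING)
        printed = make_line("A B", top=0.2, line_id="pr")
        from pathcorpus.blocks import Line, Word
        from pathcorpus.geometry import BBox

        mixed = Line(
            "mix", "P h", BBox(0.1, 0.3, 0.3, 0.018),
            (
                Word("P", BBox(0.1, 0.3, 0.05, 0.018), TextType.PRINTED),
                Word("h", BBox(0.2, 0.3, 0.05, 0.018), TextType.HANDWRITING),
            ),
        )
        page, removed = remove_handwritten_lines(make_page([hw, printed, mixed]))
        assert [l.line_id for l in removed] == ["hw"]
        assert [l.line_id for l in page.lines] == ["pr", "mix"]


class TestRegexRemoval:
    def test_page_footer_pattern(self):
        cfg = CleaningConfig(regexes=[r"PAGE \d+ OF \d+"])
        page = make_page([
            make_line("SURGICAL PATHOLOGY REPORT PAGE 1 OF 2", line_id="a"),
            make_line("TUMOR IS PRESENT", top=0.2, line_id="b"),
        ])
        page2, removed = remove_matched_lines(page, cfg)
        assert [(l.line_id, i) for l, i in removed] == [("a", 0)]
        assert [l.line_id for l in page2.lines] == ["b"]

    def test_empty_pattern_list_identity(self):
        page = make_page([make_line("ANYTHING", line_id="a")])
        page2, removed = remove_matched_lines(page, CleaningConfig())
        assert removed == [] and page2.lines == page.lines

    def test_case_insensitive_by_default(self):
        cfg = CleaningConfig(regexes=["fax"])
        _, removed = remove_matched_lines(
            make_page([make_line("FAX COVER", line_id="a")]), cfg
        )
        assert len(removed) == 1

    def test_noncompiling_pattern_named(self):
        with pytest.raises(ConfigError, match=r"\(unbalanced"):
            CleaningConfig(regexes=["(unbalanced"])

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(6)
        words = ["ALPHA", "BETA", "GAMMA", "DELTA", "EPS"]
        patterns = [rng.choice(words) for _ in range(10)]
        cfg = CleaningConfig(regexes=patterns)
        lines = []
        for i in range(100):
            text = " ".join(rng.choice(words, size=3))
            lines.append(make_line(text, top=0.001 * i + 0.01, line_id=f"l{i}"))
        page = make_page(lines)
        _, removed = remove_matched_lines(page, cfg)
        expected = {
            l.line_id
            for l in lines
            if any(re.search(p, l.text, re.IGNORECASE) for p in patterns)
        }
        assert {l.line_id for l, _ in removed} == expected

    def test_bundled_example_patterns_compile(self):
        patterns = example_cleaning_regexes()
        assert len(patterns) >= 15
        CleaningConfig(regexes=patterns)  # must not raise


class TestShortReportFlag:
    @pytest.mark.parametrize("n_lines, expect_short", [(5, True), (6, False)])
    def test_threshold(self, n_lines, expect_short):
        lines = [make_line(f"L{i}", top=0.05 + 0.03 * i, line_id=f"l{i}")
                 for i in range(n_lines)]
        doc = make_doc([make_page(lines)])
        flags = flag_short_reports(doc)
        assert (SHORT_REPORT in flags) is expect_short

    def test_zero_lines_needs_review(self):
        doc = make_doc([make_page([])])
        flags = flag_short_reports(doc)
        assert SHORT_REPORT in flags and NEEDS_REVIEW in flags


class TestAssembleText:
    def test_single_line(self):
        doc = make_doc([make_page([make_line("Specimen A", line_id="a")])])
        assert assemble_text(doc) == "Specimen A"

    def test_two_lines_period_delimiter(self):
        doc = make_doc([make_page([
            make_line("A", line_id="a"),
            make_line("B", top=0.2, line_id="b"),
        ])])
        assert assemble_text(doc) == "A. B"

    def test_two_pages_space_delimiter(self):
        doc = make_doc([
            make_page([make_line("A", line_id="a"),
                       make_line("B", top=0.2, line_id="b")], 1),
            make_page([make_line("C", line_id="c"),
                       make_line("D", top=0.2, line_id="d")], 2),
        ])
        assert assemble_text(doc) == "A. B C. D"

    def test_empty_document_empty_string(self):
        assert assemble_text(make_doc([make_page([])])) == ""

    def test_delimiters_only_add_length(self):
        doc = make_doc([make_page([
            make_line("AB", line_id="a"), make_line("CD", top=0.2, line_id="b"),
        ])])
        total = sum(len(l.text) for p in doc.pages for l in p.lines)
        assert len(assemble_text(doc)) >= total


class TestBuildCorpus:
    def _docs(self, n=3):
        return [
            make_doc([make_page([make_line(f"TEXT {i}", line_id=f"l{i}")])],
                     report_id=f"P{i}")
            for i in range(n)
        ]

    def test_full_label_coverage(self):
        docs = self._docs()
        sel = SelectionOutcome(kept=[d.report_id for d in docs])
        labels = {d.report_id: "BRCA" for d in docs}
        records, audit = build_corpus(docs, sel, labels)
        assert len(records) == 3
        assert audit.stages["corpus_assembly"].items_removed == 0

    def test_missing_label_audited(self):
        docs = self._docs()
        sel = SelectionOutcome(kept=[d.report_id for d in docs])
        labels = {"P0": "BRCA", "P1": "LUAD"}
        records, audit = build_corpus(docs, sel, labels)
        assert len(records) == 2
        stage = audit.stages["corpus_assembly"]
        assert stage.per_rule["missing_label"] == 1
        assert stage.items_in - stage.items_removed == stage.items_out == 2

    def test_missing_document_audited(self):
        docs = self._docs(2)
        sel = SelectionOutcome(kept=["P0", "P1", "P9"])
        labels = {pid: "BRCA" for pid in sel.kept}
        records, audit = build_corpus(docs, sel, labels)
        assert len(records) == 2
        assert audit.stages["corpus_assembly"].per_rule["missing_document"] == 1

    def test_jsonl_round_trip(self, tmp_path, small_corpus):
        docs, _, labels = small_corpus
        sel = SelectionOutcome(kept=[d.report_id for d in docs])
        records, _ = build_corpus(docs, sel, labels)
        path = tmp_path / "corpus.jsonl"
        write_corpus_jsonl(records, path)
        assert read_corpus_jsonl(path) == records


class TestSummarize:
    def test_counts_sum_and_order(self, small_corpus):
        docs, _, labels = small_corpus
        sel = SelectionOutcome(kept=[d.report_id for d in docs])
        records, _ = build_corpus(docs, sel, labels)
        table = summarize_corpus(records)
        assert table["n_patients"].sum() == len(records)
        assert list(table["n_patients"]) == sorted(
            table["n_patients"], reverse=True
        )

    def test_planted_per_class_counts_recovered(self):
        spec = GenSpec(seed=3, class_counts={"BRCA": 7, "COAD": 4},
                       plant_rates=PlantRates(qc_table=0))
        docs, _, labels = generate_labeled_corpus(spec)
        sel = SelectionOutcome(kept=[d.report_id for d in docs])
        records, _ = build_corpus(docs, sel, labels)
        table = summarize_corpus(records).set_index("project_label")
        assert table.loc["BRCA", "n_patients"] == 7
        assert table.loc["COAD", "n_patients"] == 4

    def test_empty_corpus(self):
        assert summarize_corpus([]).empty


class TestAuditLog:
    def test_conservation_enforced(self):
        log = AuditLog()
        log.record("s", items_in=10, items_removed=3)
        assert log.stages["s"].items_out == 7
        with pytest.raises(ValueError):
            log.record("bad", items_in=2, items_removed=5)

    def test_merging_repeated_stages(self):
        log = AuditLog()
        log.record("s", 10, 2, {"r0": 2})
        log.record("s", 5, 1, {"r0": 1})
        stage = log.stages["s"]
        assert (stage.items_in, stage.items_removed) == (15, 3)
        assert stage.per_rule == {"r0": 3}


class TestPipelineIdempotence:
    def test_cleaning_clean_documents_removes_nothing(self):
        """Second pass over already-cleaned documents is a no-op."""
        spec = GenSpec(seed=11, n_reports=10,
                       plant_rates=PlantRates(qc_table=0.3,
                                              handwriting_line=0.2,
                                              header_line=0.2))
        docs, _, _ = generate_labeled_corpus(spec)
        cfg = CleaningConfig(regexes=example_cleaning_regexes())
        for doc in docs:
            audit1, audit2 = AuditLog(), AuditLog()
            once = clean_document(doc, cfg, audit1)
            twice = clean_document(once, cfg, audit2)
            assert twice == once
            assert audit2.stages["handwriting_removal"].items_removed == 0
            assert audit2.stages["regex_removal"].items_removed == 0


class TestCorpusRecord:
    def test_empty_text_requires_flag(self):
        with pytest.raises(ValueError):
            CorpusRecord("P1", "BRCA", "")
        CorpusRecord("P1", "BRCA", "", flags=frozenset({NEEDS_REVIEW}))
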