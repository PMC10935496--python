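"""Shared fixtures: quick line/page builders and small generated corpora."""

from __future__ import annotations

import pytest

from pathcorpus.blocks import Line, OcrDocument, Page, TextType, Word
from pathcorpus.geometry import BBox


def make_word(text: str, left: float, top: float, width: float,
              height: float = 0.018,
              text_type: TextType = TextType.PRINTED) -> Word:
    return Word(text=text, bbox=BBox(left, top, width, height),
                text_type=text_type)


def make_line(text: str, left: float = 0.1, top: float = 0.1,
              width: float = 0.3, height: float = 0.018,
              line_id: str = "L1",
              text_type: TextType = TextType.PRINTED) -> Line:
    """A line whose words split the box proportionally by character."""
    tokens = [t for t in text.split(" ") if t]
    n = max(len(text), 1)
    char_w = width / n
    words = []
    cursor = 0
    for tok in tokens:
        words.append(make_word(tok, left + cursor * char_w, top,
                               len(tok) * char_w, height, text_type))
        cursor += len(tok) + 1
    return Line(line_id=line_id, text=" ".join(tokens),
                bbox=BBox(left, top, width, height), words=tuple(words))


def make_page(lines, page_number: int = 1, tables=(), sels=()) -> Page:
    return Page(page_number=page_number, lines=tuple(lines),
                tables=tuple(tables), selection_elements=tuple(sels))


def make_doc(pages, report_id: str = "R1") -> OcrDocument:
    return OcrDocument(report_id=report_id, pages=tuple(pages))


@pytest.fixture(scope="session")
def synthetic_headers():
    from pathcorpus.simulate import default_synthetic_headers

    return default_synthetic_headers()


@pytest.fixture(scope="session")
def small_corpus():
    """60 mixed-label reports, 1-3 pages, half the pages carry a QC table."""
    from pathcorpus.simulate import GenSpec, generate_labeled_corpus

    spec = GenSpec(seed=42, n_reports=60, pages_min=1, pages_max=3)
    return generate_labeled_corpus(spec)
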