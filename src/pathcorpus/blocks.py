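"""Domain model for OCR block documents and a reader/writer for the
Textract-dialect JSON they arrive in.

A document is a list of pages; a page holds ordered lines (each an ordered
list of words with a text-type annotation), table regions, and selection
elements (checkbox-like marks). The reader is deliberately tolerant:
unknown block types are counted and skipped, blocks missing geometry are
rejected with a log message, and words missing a text-type annotation
default to PRINTED so that absent annotation can never cause text loss.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from .geometry import BBox

logger = logging.getLogger(__name__)


class OcrParseError(ValueError):
    """Malformed input JSON (reports the byte/char offset when known)."""


class EmptyDocumentError(ValueError):
    """The input contained no pages."""


class TextType(str, enum.Enum):
    PRINTED = "PRINTED"
    HANDWRITING = "HANDWRITING"


class SelectionStatus(str, enum.Enum):
    SELECTED = "SELECTED"
    NOT_SELECTED = "NOT_SELECTED"


@dataclass(frozen=True)
class Word:
    text: str
    bbox: BBox
    text_type: TextType = TextType.PRINTED
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("Word.text must be non-empty after stripping")
        if self.confidence is not None and not 0 <= self.confidence <= 100:
            raise ValueError(f"confidence out of [0,100]: {self.confidence}")


@dataclass(frozen=True)
class Line:
    line_id: str
    text: str
    bbox: BBox
    words: tuple[Word, ...] = ()

    def __post_init__(self) -> None:
        if self.words:
            joined = " ".join(w.text for w in self.words)
            if joined != self.text:
                raise ValueError(
                    f"line {self.line_id!r}: text {self.text!r} != joined "
                    f"word texts {joined!r}"
                )
            for w in self.words:
                if not self.bbox.contains(w.bbox, eps=1e-3):
                    raise ValueError(
                        f"line {self.line_id!r}: word box {w.bbox} outside "
                        f"line box {self.bbox}"
                    )

    @property
    def is_handwritten_only(self) -> bool:
        """True when every word is handwriting and the line has words."""
        return bool(self.words) and all(
            w.text_type is TextType.HANDWRITING for w in self.words
        )


@dataclass(frozen=True)
class SelectionElement:
    bbox: BBox
    status: SelectionStatus


@dataclass(frozen=True)
class Page:
    page_number: int
    lines: tuple[Line, ...] = ()
    tables: tuple[BBox, ...] = ()
    selection_elements: tuple[SelectionElement, ...] = ()

    def __post_init__(self) -> None:
        if self.page_number < 1:
            raise ValueError("page_number is 1-based")

    @property
    def text(self) -> str:
        """All line text on the page, space-joined in reading order."""
        return " ".join(line.text for line in self.lines)


@dataclass(frozen=True)
class OcrDocument:
    report_id: str
    pages: tuple[Page, ...]

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if not self.pages:
            raise EmptyDocumentError(f"document {self.report_id!r} has no pages")
        numbers = [p.page_number for p in self.pages]
        if len(set(numbers)) != len(numbers):
            raise ValueError(f"duplicate page numbers in {self.report_id!r}")

    @property
    def n_lines(self) -> int:
        return sum(len(p.lines) for p in self.pages)


_KNOWN_TYPES = {"PAGE", "LINE", "WORD", "TABLE", "CELL", "SELECTION_ELEMENT"}


def _parse_bbox(block: dict) -> BBox | None:
    geom = block.get("Geometry", {}).get("BoundingBox")
    if geom is None:
        return None
    try:
        return BBox(
            float(geom["Left"]), float(geom["Top"]),
            float(geom["Width"]), float(geom["Height"]),
        )
    except (KeyError, TypeError, ValueError):
        return None


def parse_blocks(blocks: list[dict], report_id: str) -> OcrDocument:
    """Assemble an :class:`OcrDocument` from a Textract-dialect block list.

    PAGE blocks (or, failing that, the 1-based ``Page`` attribute) define
    page boundaries. LINE blocks bind their WORD children through CHILD
    relationship arrays; words not referenced by any line are dropped.
    """
    ignored: dict[str, int] = {}
    rejected = 0
    defaulted_text_type = 0

    by_id: dict[str, dict] = {b["Id"]: b for b in blocks if "Id" in b}
    page_numbers: set[int] = set()
    for b in blocks:
        btype = b.get("BlockType")
        if btype == "PAGE":
            page_numbers.add(int(b.get("Page", 1)))

    words: dict[str, Word] = {}
    for b in blocks:
        if b.get("BlockType") != "WORD":
            continue
        bbox = _parse_bbox(b)
        if bbox is None:
            rejected += 1
            continue
        raw_tt = b.get("TextType")
        if raw_tt is None:
            defaulted_text_type += 1
            tt = TextType.PRINTED
        else:
            tt = TextType(raw_tt)
        text = str(b.get("Text", "")).strip()
        if not text:
            rejected += 1
            continue
        words[b["Id"]] = Word(
            text=text, bbox=bbox, text_type=tt,
            confidence=b.get("Confidence"),
        )

    pages_accum: dict[int, dict] = {}

    def page_slot(num: int) -> dict:
        return pages_accum.setdefault(
            num, {"lines": [], "tables": [], "sels": []}
        )

    for b in blocks:
        btype = b.get("BlockType")
        pnum = int(b.get("Page", 1))
        if btype == "PAGE":
            page_slot(pnum)
        elif btype == "LINE":
            bbox = _parse_bbox(b)
            if bbox is None:
                rejected += 1
                continue
            child_ids: list[str] = []
            for rel in b.get("Relationships", []) or []:
                if rel.get("Type") == "CHILD":
                    child_ids.extend(rel.get("Ids", []))
            line_words = tuple(words[i] for i in child_ids if i in words)
            text = str(b.get("Text", "")).strip()
            if line_words and not text:
                text = " ".join(w.text for w in line_words)
            if not text:
                rejected += 1
                continue
            page_slot(pnum)["lines"].append(
                Line(line_id=b.get("Id", f"line-{pnum}-{len(page_slot(pnum)['lines'])}"),
                     text=text, bbox=bbox, words=line_words)
            )
        elif btype == "TABLE":
            bbox = _parse_bbox(b)
            if bbox is None:
                rejected += 1
                continue
            page_slot(pnum)["tables"].append(bbox)
        elif btype == "SELECTION_ELEMENT":
            bbox = _parse_bbox(b)
            if bbox is None:
                rejected += 1
                continue
            status = SelectionStatus(b.get("SelectionStatus", "NOT_SELECTED"))
            page_slot(pnum)["sels"].append(SelectionElement(bbox=bbox, status=status))
        elif btype in ("WORD", "CELL"):
            # words handled above; cell structure is out of scope
            continue
        else:
            ignored[str(btype)] = ignored.get(str(btype), 0) + 1

    if ignored:
        logger.info("%s: ignored unknown block types %s", report_id, ignored)
    if rejected:
        logger.warning("%s: rejected %d blocks missing geometry/text", report_id, rejected)
    if defaulted_text_type:
        logger.info(
            "%s: %d words lacked TextType, defaulted to PRINTED",
            report_id, defaulted_text_type,
        )

    if not pages_accum:
        raise EmptyDocumentError(f"no pages in input for {report_id!r}")

    pages = tuple(
        Page(
            page_number=num,
            lines=tuple(slot["lines"]),
            tables=tuple(slot["tables"]),
            selection_elements=tuple(slot["sels"]),
        )
        for num, slot in sorted(pages_accum.items())
    )
    return OcrDocument(report_id=report_id, pages=pages)


def read_ocr_document(path: Union[str, Path], report_id: str) -> OcrDocument:
    """Read one report's OCR block JSON file into an :class:`OcrDocument`."""
    raw = Path(path).read_text(encoding="utf-8")
    try:
        obj = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise OcrParseError(
            f"{path}: malformed JSON at char offset {exc.pos}: {exc.msg}"
        ) from exc
    blocks = obj.get("Blocks")
    if not isinstance(blocks, list):
        raise OcrParseError(f"{path}: missing top-level 'Blocks' array")
    return parse_blocks(blocks, report_id=report_id)


def _bbox_json(b: BBox) -> dict:
    return {"BoundingBox": {"Left": b.left, "Top": b.top,
                            "Width": b.width, "Height": b.height}}


def document_to_blocks(doc: OcrDocument) -> list[dict]:
    """Serialize a document back to the block dialect (stage-to-stage piping)."""
    blocks: list[dict] = []
    counter = 0

    def next_id(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}-{counter:06d}"

    for page in doc.pages:
        blocks.append({
            "BlockType": "PAGE",
            "Id": next_id("page"),
            "Page": page.page_number,
            "Geometry": _bbox_json(BBox(0, 0, 1, 1)),
        })
        for line in page.lines:
            word_ids = [next_id("word") for _ in line.words]
            line_block = {
                "BlockType": "LINE",
                "Id": line.line_id,
                "Page": page.page_number,
                "Text": line.text,
                "Geometry": _bbox_json(line.bbox),
            }
            if word_ids:
                line_block["Relationships"] = [{"Type": "CHILD", "Ids": word_ids}]
            blocks.append(line_block)
            for wid, word in zip(word_ids, line.words):
                wb = {
                    "BlockType": "WORD",
                    "Id": wid,
                    "Page": page.page_number,
                    "Text": word.text,
                    "TextType": word.text_type.value,
                    "Geometry": _bbox_json(word.bbox),
                }
                if word.confidence is not None:
                    wb["Confidence"] = word.confidence
                blocks.append(wb)
        for tb in page.tables:
            blocks.append({
                "BlockType": "TABLE",
                "Id": next_id("table"),
                "Page": page.page_number,
                "Geometry": _bbox_json(tb),
            })
        for sel in page.selection_elements:
            blocks.append({
                "BlockType": "SELECTION_ELEMENT",
                "Id": next_id("sel"),
                "Page": page.page_number,
                "SelectionStatus": sel.status.value,
                "Geometry": _bbox_json(sel.bbox),
            })
    return blocks


def write_ocr_document(doc: OcrDocument, path: Union[str, Path]) -> None:
    """Write a document as Textract-dialect JSON (deterministic bytes)."""
    payload = {"Blocks": document_to_blocks(doc)}
    Path(path).write_text(
        json.dumps(payload, sort_keys=True, separators=(",", ":")),
        encoding="utf-8",
    )
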