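"""Detection and excision of sample-quality-control tables.

TCGA inserted a small metadata table into report scans recording slide and
sample quality (tumor nuclei percentage, necrosis, and similar). These
tables are irrelevant for diagnosis and absent from routine clinical
reports, so they must be cut out of the text. Detection anchors on the
table's section-header keywords: each header line that fuzzy-matches a
configured keyword contributes a custom bounding box (the line's box grown
by per-keyword offsets, encoding the header's consistent position relative
to the table body); the union hull of these boxes -- the *max bounding
box* -- localizes the whole table. A single matched header suffices: the
header vocabulary is distinct enough from diagnostic prose that lone
matches are reliable. Lines overlapping the max box by at least the
overlap threshold (default 0.25 of the line's own area) are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .blocks import Line, OcrDocument, Page
from .fuzzy import KeywordSpec, fuzzy_find
from .geometry import BBox, Offsets, expand_box, merge_boxes, overlap_fraction

logger = logging.getLogger(__name__)

DEFAULT_OVERLAP_THRESHOLD = 0.25
DEFAULT_AREA_CAP = 0.6


@dataclass(frozen=True)
class HeaderSpec:
    """One QC-table section header: the keyword plus the box growth that
    extends the header line over the table region it labels."""

    keyword: KeywordSpec
    offsets: Offsets = Offsets()


@dataclass
class TableDetection:
    page_number: int
    matched_headers: list[tuple[str, str, int]]  # (keyword, line_id, distance)
    max_box: BBox
    removed_line_ids: list[str] = field(default_factory=list)
    large_box_flag: bool = False


def detect_qc_table(
    page: Page, headers: Sequence[HeaderSpec]
) -> Optional[TableDetection]:
    """Locate a QC table on a page, or return None.

    Each header keyword is fuzzy-matched against every line's text; each
    hit contributes the line's box expanded by that header's offsets. Any
    single hit is sufficient for a detection; the max box is the merge of
    all hit boxes.
    """
    if not headers:
        raise ValueError("at least one HeaderSpec is required")
    matched: list[tuple[str, str, int]] = []
    boxes: list[BBox] = []
    for line in page.lines:
        for header in headers:
            hits = fuzzy_find(line.text, header.keyword)
            if hits:
                best = min(h.distance for h in hits)
                matched.append((header.keyword.phrase, line.line_id, best))
                boxes.append(expand_box(line.bbox, header.offsets))
    if not boxes:
        return None
    return TableDetection(
        page_number=page.page_number,
        matched_headers=matched,
        max_box=merge_boxes(boxes),
    )


def remove_table_lines(
    page: Page,
    max_box: BBox,
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> tuple[Page, list[Line]]:
    """Remove lines overlapping the max box by >= threshold of their area.

    The threshold is inclusive (a line at exactly the minimum overlap is
    removed). Degenerate zero-area line boxes cannot be scored and are
    kept with a log message. Survivor order is preserved.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    kept: list[Line] = []
    removed: list[Line] = []
    degenerate = 0
    for line in page.lines:
        if line.bbox.area <= 0:
            degenerate += 1
            kept.append(line)
            continue
        if overlap_fraction(line.bbox, max_box) >= threshold:
            removed.append(line)
        else:
            kept.append(line)
    if degenerate:
        logger.warning(
            "page %d: kept %d zero-area lines (cannot score overlap)",
            page.page_number, degenerate,
        )
    new_page = Page(
        page_number=page.page_number,
        lines=tuple(kept),
        tables=page.tables,
        selection_elements=page.selection_elements,
    )
    return new_page, removed


def flag_large_boxes(
    detections: Sequence[TableDetection],
    area_cap: float = DEFAULT_AREA_CAP,
) -> list[TableDetection]:
    """Flag detections whose max box covers more than *area_cap* of the
    page. Flags feed a review roster -- an oversized box suggests a header
    keyword matched main text -- and never trigger removal by themselves."""
    for d in detections:
        d.large_box_flag = d.max_box.area > area_cap
    return list(detections)


def remove_qc_tables(
    doc: OcrDocument,
    headers: Sequence[HeaderSpec],
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    area_cap: float = DEFAULT_AREA_CAP,
) -> tuple[OcrDocument, list[TableDetection]]:
    """Detect and excise QC tables on every page of a document."""
    new_pages: list[Page] = []
    detections: list[TableDetection] = []
    for page in doc.pages:
        det = detect_qc_table(page, headers)
        if det is None:
            new_pages.append(page)
            continue
        new_page, removed = remove_table_lines(page, det.max_box, threshold)
        det.removed_line_ids = [l.line_id for l in removed]
        detections.append(det)
        new_pages.append(new_page)
    flag_large_boxes(detections, area_cap)
    return OcrDocument(report_id=doc.report_id, pages=tuple(new_pages)), detections
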