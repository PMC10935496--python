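"""Synthetic OCR-document and metadata generator with ground truth.

Every pipeline stage needs realistic inputs that cannot ship with the
package: multi-page OCR block documents containing a planted
quality-control table (section headers at consistent relative positions,
optionally typo-corrupted), handwriting-annotated insertion lines,
checkbox-dense multiple-choice form pages, clinic-header boilerplate
lines, placeholder/discrepancy banner reports, and diagnostic body text
carrying a per-cancer-type vocabulary signal. This module generates all
of them deterministically from a seed, together with a
:class:`GroundTruth` recording what was planted where, so detection
stages can be scored against exact truth.

The generator's QC section-header list is its own (nine plausible slide
and sample-quality headers); detection is configured from
:func:`default_synthetic_headers` and tests are agnostic to the specific
phrases.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .blocks import (
    Line,
    OcrDocument,
    Page,
    SelectionElement,
    SelectionStatus,
    TextType,
    Word,
)
from .cases import CaseRecord
from .forms import COLON_FORM_FILTER
from .fuzzy import KeywordSpec
from .geometry import BBox, Offsets, merge_boxes
from .qc_tables import HeaderSpec
from .screening import DISCREPANCY_FORM_PHRASE, MISSING_FORM_PHRASE

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PlantRates:
    """Per-page (qc_table, form_page) and per-line (handwriting_line,
    header_line) plant probabilities, plus per-report verdict-class rates
    for the screening stage."""

    qc_table: float = 0.5
    form_page: float = 0.0
    handwriting_line: float = 0.1
    header_line: float = 0.15
    missing_form: float = 0.0
    discrepancy_form: float = 0.0
    poor_scan: float = 0.0

    def __post_init__(self) -> None:
        for name in ("qc_table", "form_page", "handwriting_line",
                     "header_line", "missing_form", "discrepancy_form",
                     "poor_scan"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"rate {name}={v} outside [0,1]")


#: Cancer-type vocabularies for body text. Disjoint term sets per class so
#: that classification difficulty is controlled by construction.
DEFAULT_VOCABULARY: dict[str, tuple[str, ...]] = {
    "BRCA": ("ductal carcinoma", "lobular carcinoma", "breast parenchyma",
             "estrogen receptor positive", "axillary lymph node",
             "nipple margin", "fibrocystic change"),
    "LUAD": ("pulmonary adenocarcinoma", "bronchial margin", "visceral pleura",
             "lobectomy specimen", "hilar lymph node", "alveolar spaces",
             "peribronchial tissue"),
    "COAD": ("colonic adenocarcinoma", "sigmoid colon", "cecal mass",
             "mesenteric nodes", "pericolonic fat", "muscularis propria",
             "tubulovillous adenoma"),
    "KIRC": ("clear cell renal carcinoma", "radical nephrectomy",
             "perinephric fat", "renal vein", "gerota fascia",
             "renal pelvis", "fuhrman grade"),
}


@dataclass(frozen=True)
class GenSpec:
    """Full description of a synthetic corpus.

    ``class_counts`` gives the number of reports per cancer-type label;
    ``vocabulary`` must cover every label. ``typo_rate`` is the chance a
    planted QC header is corrupted, by at most ``max_typo_edits`` edits
    (kept within each header's fuzzy allowance by default, so planted
    tables remain detectable).
    """

    seed: int = 0
    n_reports: int = 10
    pages_min: int = 1
    pages_max: int = 3
    class_counts: Optional[Mapping[str, int]] = None
    plant_rates: PlantRates = PlantRates()
    typo_rate: float = 0.3
    max_typo_edits: int = 1
    vocabulary: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_VOCABULARY)
    )
    body_lines_min: int = 4
    body_lines_max: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.typo_rate <= 1:
            raise ValueError("typo_rate outside [0,1]")
        if self.max_typo_edits < 0:
            raise ValueError("max_typo_edits must be >= 0")
        if self.pages_min < 1 or self.pages_max < self.pages_min:
            raise ValueError("invalid page range")


class LineRole(str, enum.Enum):
    BODY = "BODY"
    QC_TABLE = "QC_TABLE"
    HANDWRITING = "HANDWRITING"
    HEADER = "HEADER"


@dataclass
class PageTruth:
    page_number: int
    form_page: bool = False
    qc_box: Optional[BBox] = None
    qc_line_ids: list[str] = field(default_factory=list)
    line_roles: dict[str, LineRole] = field(default_factory=dict)


@dataclass
class GroundTruth:
    report_id: str
    verdict: str  # a screening.Verdict value
    pages: list[PageTruth] = field(default_factory=list)


# ---------------------------------------------------------------------------
# QC table geometry (generator-owned header list)

_QC_HEADERS: tuple[str, ...] = (
    "TOP SLIDE", "BOTTOM SLIDE", "PERCENT TUMOR NUCLEI",
    "PERCENT NECROSIS", "PERCENT STROMAL CELLS", "TUMOR WEIGHT",
    "SAMPLE PORTION", "SLIDE REVIEWER", "PERCENT NORMAL CELLS",
)

#: Expansion offsets shared by the synthetic headers: headers sit in the
#: top three rows of the table, values in the two rows below, so each
#: header box reaches right and down to cover the block it labels.
_QC_OFFSETS = Offsets(left=0.02, right=0.10, up=0.01, down=0.12)

_ROW_H = 0.03        # vertical pitch of layout rows
_LINE_H = 0.018      # line box height
_TOP_MARGIN = 0.06
_MAX_ROWS = 29       # last row top at 0.90


def default_synthetic_headers(allowance: Optional[int] = None) -> list[HeaderSpec]:
    """Header specs matching the generator's planted QC tables.

    Short headers get allowance 1, longer ones 2 (longer phrases absorb
    more OCR noise); pass ``allowance`` to pin a single value.
    """
    specs = []
    for phrase in _QC_HEADERS:
        k = allowance if allowance is not None else (1 if len(phrase) < 14 else 2)
        specs.append(HeaderSpec(KeywordSpec(phrase, k), _QC_OFFSETS))
    return specs


class PageOverflowError(RuntimeError):
    """A requested plant did not fit on the page."""


# ---------------------------------------------------------------------------
# low-level builders

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def _corrupt(rng: np.random.Generator, text: str, n_edits: int) -> str:
    """Apply up to n_edits random single-character edits."""
    chars = list(text)
    for _ in range(n_edits):
        if not chars:
            break
        op = rng.integers(0, 3)
        pos = int(rng.integers(0, len(chars)))
        if op == 0:  # substitute
            chars[pos] = _ALPHABET[int(rng.integers(0, 26))]
        elif op == 1 and len(chars) > 3:  # delete (keep phrase recognizable)
            del chars[pos]
        else:  # insert
            chars.insert(pos, _ALPHABET[int(rng.integers(0, 26))])
    return "".join(chars) or text


def _make_line(
    line_id: str,
    text: str,
    row: int,
    left: float = 0.08,
    max_width: float = 0.84,
    text_type: TextType = TextType.PRINTED,
) -> Line:
    """Lay out a text line at a layout row with proportional word boxes."""
    top = _TOP_MARGIN + row * _ROW_H
    n = len(text)
    width = min(max_width, max(0.04, 0.0105 * n))
    char_w = width / max(n, 1)
    words: list[Word] = []
    cursor = 0
    for token in text.split(" "):
        if token:
            x = left + cursor * char_w
            words.append(
                Word(
                    text=token,
                    bbox=BBox(x, top, len(token) * char_w, _LINE_H),
                    text_type=text_type,
                )
            )
        cursor += len(token) + 1
    return Line(
        line_id=line_id,
        text=" ".join(t for t in text.split(" ") if t),
        bbox=BBox(left, top, width, _LINE_H),
        words=tuple(words),
    )


def _body_text(rng: np.random.Generator, vocab: Sequence[str]) -> str:
    term = vocab[int(rng.integers(0, len(vocab)))].upper()
    template = int(rng.integers(0, 4))
    if template == 0:
        return f"INVASIVE {term}, GRADE {int(rng.integers(1, 4))}"
    if template == 1:
        return f"TUMOR SIZE {rng.integers(1, 9)}.{rng.integers(0, 10)} CM, {term}"
    if template == 2:
        return f"MARGINS FREE OF TUMOR, {term} IDENTIFIED"
    return f"MICROSCOPIC EXAMINATION SHOWS {term}"


_HEADER_TEMPLATES = (
    "PAGE {a} OF {b}",
    "FAX: (212) 555-01{a:02d}",
    "ACCESSION #SP-88{a:03d}",
    "PRINTED BY PATHOLOGY WORKSTATION {a}",
)

# handwritten-annotation vocabulary; deliberately disjoint from the QC
# section-header terms so planted tables stay the only fuzzy-matchable text
_HANDWRITING_TOKENS = ("rcvd", "case", "ok", "see", "note", "id", "tcga",
                       "chart", "init", "db")


def _handwriting_text(rng: np.random.Generator) -> str:
    n = int(rng.integers(2, 5))
    idx = rng.integers(0, len(_HANDWRITING_TOKENS), size=n)
    return " ".join(_HANDWRITING_TOKENS[i] for i in idx)


# ---------------------------------------------------------------------------
# page assembly


def _plant_qc_table(
    rng: np.random.Generator,
    spec: GenSpec,
    page_num: int,
    start_row: int,
    next_id,
) -> tuple[list[Line], dict[str, LineRole], BBox, int]:
    """Place the 9-header QC table starting at start_row.

    Layout: 3 rows x 3 columns of headers, then 2 value rows; returns the
    lines, their roles, the ground-truth hull box, and the next free row
    (including a clearance gap below the expanded header boxes).
    """
    # 3 header rows + 2 value rows + 3 clearance rows must fit
    if start_row + 8 > _MAX_ROWS:
        raise PageOverflowError(
            f"QC table does not fit at row {start_row} on page {page_num}"
        )
    lines: list[Line] = []
    roles: dict[str, LineRole] = {}
    cols = (0.10, 0.40, 0.70)
    order = rng.permutation(9)
    for slot, hidx in enumerate(order):
        phrase = _QC_HEADERS[hidx]
        text = phrase
        if rng.random() < spec.typo_rate:
            allowance = 1 if len(phrase) < 14 else 2
            n_edits = min(spec.max_typo_edits, allowance)
            text = _corrupt(rng, phrase, n_edits)
        row = start_row + slot // 3
        col = cols[slot % 3]
        line = _make_line(next_id(), text, row, left=col, max_width=0.24)
        lines.append(line)
        roles[line.line_id] = LineRole.QC_TABLE
    for vrow in range(2):
        vals = " ".join(str(int(rng.integers(0, 100))) for _ in range(6))
        line = _make_line(next_id(), vals, start_row + 3 + vrow, left=0.10,
                          max_width=0.70)
        lines.append(line)
        roles[line.line_id] = LineRole.QC_TABLE
    truth_box = merge_boxes([l.bbox for l in lines])
    return lines, roles, truth_box, start_row + 8


def _form_page(
    rng: np.random.Generator, page_num: int, next_id
) -> tuple[Page, PageTruth]:
    """A multiple-choice form page: keyword question lines plus a dense
    field of selection elements."""
    lines: list[Line] = []
    roles: dict[str, LineRole] = {}
    keywords = [k.phrase for k in COLON_FORM_FILTER.keywords]
    n_q = int(rng.integers(4, 7))
    chosen = rng.permutation(len(keywords))[:n_q]
    row = 0
    for qi in chosen:
        q = _make_line(next_id(), keywords[qi].upper(), row, left=0.08)
        lines.append(q)
        roles[q.line_id] = LineRole.BODY
        opts = _make_line(next_id(), "YES NO INDETERMINATE NOT EVALUATED",
                          row + 1, left=0.14)
        lines.append(opts)
        roles[opts.line_id] = LineRole.BODY
        row += 3
    n_sel = int(rng.integers(12, 25))
    sels = []
    for _ in range(n_sel):
        x = float(rng.uniform(0.05, 0.92))
        y = float(rng.uniform(0.05, 0.92))
        status = (SelectionStatus.SELECTED if rng.random() < 0.3
                  else SelectionStatus.NOT_SELECTED)
        sels.append(SelectionElement(BBox(x, y, 0.015, 0.012), status))
    page = Page(page_number=page_num, lines=tuple(lines),
                selection_elements=tuple(sels))
    truth = PageTruth(page_number=page_num, form_page=True, line_roles=roles)
    return page, truth


def _banner_page(page_num: int, phrase: str, next_id) -> tuple[Page, PageTruth]:
    """A placeholder/discrepancy banner page."""
    lines = [
        _make_line(next_id(), phrase.upper(), 2, left=0.15),
        _make_line(next_id(), "CASE DOCUMENTATION NOT AVAILABLE", 4, left=0.15),
        _make_line(next_id(), "COMPLETED BY TISSUE SOURCE SITE", 6, left=0.15),
    ]
    roles = {l.line_id: LineRole.BODY for l in lines}
    page = Page(page_number=page_num, lines=tuple(lines))
    return page, PageTruth(page_number=page_num, line_roles=roles)


def _content_page(
    rng: np.random.Generator,
    spec: GenSpec,
    label: str,
    page_num: int,
    next_id,
    force_qc: Optional[bool] = None,
) -> tuple[Page, PageTruth]:
    """An ordinary diagnostic page, optionally with a planted QC table and
    sprinkled handwriting/clinic-header lines."""
    vocab = spec.vocabulary[label]
    truth = PageTruth(page_number=page_num)
    lines: list[Line] = []

    plant_qc = (rng.random() < spec.plant_rates.qc_table
                if force_qc is None else force_qc)
    n_body = int(rng.integers(spec.body_lines_min, spec.body_lines_max + 1))
    qc_after = int(rng.integers(1, max(2, n_body))) if plant_qc else -1

    row = 0
    placed = 0
    while placed < n_body and row < _MAX_ROWS:
        if placed == qc_after and plant_qc:
            # one clearance row above, table block, clearance below
            try:
                qc_lines, qc_roles, qc_box, row = _plant_qc_table(
                    rng, spec, page_num, row + 1, next_id
                )
            except PageOverflowError:
                qc_after = -2  # table no longer fits; skip planting
                plant_qc = False
                continue
            lines.extend(qc_lines)
            truth.line_roles.update(qc_roles)
            truth.qc_box = qc_box
            truth.qc_line_ids = list(qc_roles)
            qc_after = -1
            continue
        r = rng.random()
        if r < spec.plant_rates.handwriting_line:
            line = _make_line(next_id(), _handwriting_text(rng), row,
                              text_type=TextType.HANDWRITING)
            truth.line_roles[line.line_id] = LineRole.HANDWRITING
        elif r < spec.plant_rates.handwriting_line + spec.plant_rates.header_line:
            tmpl = _HEADER_TEMPLATES[int(rng.integers(0, len(_HEADER_TEMPLATES)))]
            line = _make_line(
                next_id(), tmpl.format(a=int(rng.integers(1, 99)),
                                       b=int(rng.integers(1, 9))), row
            )
            truth.line_roles[line.line_id] = LineRole.HEADER
        else:
            line = _make_line(next_id(), _body_text(rng, vocab), row)
            truth.line_roles[line.line_id] = LineRole.BODY
            placed += 1
        lines.append(line)
        row += 1

    page = Page(page_number=page_num, lines=tuple(lines))
    return page, truth


# ---------------------------------------------------------------------------
# public generators


def generate_report(
    spec: GenSpec, label: str, index: int = 0
) -> tuple[OcrDocument, GroundTruth]:
    """Generate one report (deterministic in (spec.seed, index)).

    The report-level verdict class (ordinary / missing-pathology banner /
    discrepancy banner / poor scan) is drawn from the plant rates; page
    content follows the verdict.
    """
    if label not in spec.vocabulary:
        raise KeyError(f"no vocabulary for label {label!r}")
    rng = np.random.default_rng([spec.seed, index])
    report_id = f"TCGA-SYN-{index:05d}"
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{report_id}-L{counter:04d}"

    u = rng.random()
    pr = spec.plant_rates
    if u < pr.missing_form:
        verdict = "MISSING_FORM"
    elif u < pr.missing_form + pr.discrepancy_form:
        verdict = "DISCREPANCY_FORM"
    elif u < pr.missing_form + pr.discrepancy_form + pr.poor_scan:
        verdict = "POOR_SCAN"
    else:
        verdict = "OK"

    truth = GroundTruth(report_id=report_id, verdict=verdict)
    if verdict == "MISSING_FORM":
        page, pt = _banner_page(1, MISSING_FORM_PHRASE, next_id)
        truth.pages.append(pt)
        return OcrDocument(report_id, (page,)), truth
    if verdict == "DISCREPANCY_FORM":
        page, pt = _banner_page(1, DISCREPANCY_FORM_PHRASE, next_id)
        truth.pages.append(pt)
        return OcrDocument(report_id, (page,)), truth

    n_pages = int(rng.integers(spec.pages_min, spec.pages_max + 1))
    pages: list[Page] = []
    for pnum in range(1, n_pages + 1):
        if rng.random() < pr.form_page:
            page, pt = _form_page(rng, pnum, next_id)
        else:
            page, pt = _content_page(rng, spec, label, pnum, next_id)
        pages.append(page)
        truth.pages.append(pt)
    return OcrDocument(report_id, tuple(pages)), truth


def generate_labeled_corpus(
    spec: GenSpec,
) -> tuple[list[OcrDocument], list[GroundTruth], dict[str, str]]:
    """Generate a labeled corpus with the per-class counts in the spec.

    Without explicit ``class_counts``, reports are spread evenly over the
    vocabulary's labels.
    """
    if spec.class_counts is not None:
        plan = [(lbl, n) for lbl, n in spec.class_counts.items()]
    else:
        labels = sorted(spec.vocabulary)
        base = spec.n_reports // len(labels)
        extra = spec.n_reports % len(labels)
        plan = [(lbl, base + (1 if i < extra else 0))
                for i, lbl in enumerate(labels)]
    docs: list[OcrDocument] = []
    truths: list[GroundTruth] = []
    labels_out: dict[str, str] = {}
    index = 0
    for lbl, n in plan:
        for _ in range(n):
            doc, truth = generate_report(spec, lbl, index)
            docs.append(doc)
            truths.append(truth)
            labels_out[doc.report_id] = lbl
            index += 1
    return docs, truths, labels_out


def generate_case_table(
    counts: Mapping[str, int],
    seed: int = 0,
    labels: Sequence[str] = ("BRCA", "LUAD", "COAD", "KIRC"),
) -> list[CaseRecord]:
    """Case-metadata table with exact, disjoint planted exclusion
    categories.

    ``counts`` keys: ``clean``, ``multi_report``, ``non_primary``,
    ``no_survival``, ``no_report`` (missing keys default to 0). Each
    planted patient qualifies for exactly one category, so downstream
    selection arithmetic is exact.
    """
    rng = np.random.default_rng(seed)
    records: list[CaseRecord] = []
    pid_counter = 0

    def next_pid() -> str:
        nonlocal pid_counter
        pid_counter += 1
        return f"PT-{pid_counter:05d}"

    def label_for(i: int) -> str:
        return labels[i % len(labels)]

    for _ in range(counts.get("clean", 0)):
        pid = next_pid()
        records.append(CaseRecord(pid, "Primary Tumor", f"RPT-{pid}", True,
                                  label_for(pid_counter)))
    for _ in range(counts.get("multi_report", 0)):
        pid = next_pid()
        records.append(CaseRecord(pid, "Primary Tumor", f"RPT-{pid}-A", True,
                                  label_for(pid_counter)))
        records.append(CaseRecord(pid, "Primary Tumor", f"RPT-{pid}-B", True,
                                  label_for(pid_counter)))
    for _ in range(counts.get("non_primary", 0)):
        pid = next_pid()
        records.append(CaseRecord(pid, "Metastatic", f"RPT-{pid}", True,
                                  label_for(pid_counter)))
    for _ in range(counts.get("no_survival", 0)):
        pid = next_pid()
        records.append(CaseRecord(pid, "Primary Tumor", f"RPT-{pid}", False,
                                  label_for(pid_counter)))
    for _ in range(counts.get("no_report", 0)):
        pid = next_pid()
        records.append(CaseRecord(pid, "Primary Tumor", None, True,
                                  label_for(pid_counter)))
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def generate_screening_corpus(
    n_total: int,
    n_missing: int,
    n_discrepancy: int,
    n_poor: int,
    seed: int = 0,
    label: str = "BRCA",
) -> tuple[list[OcrDocument], set[str], list[GroundTruth]]:
    """A corpus with exact verdict-class counts for screening arithmetic.

    Returns (documents, poor-scan id set, ground truths). Ordinary
    reports are single-page diagnostic documents; banner reports carry
    the missing/discrepancy phrase verbatim; poor-scan reports look
    ordinary and are identified only by the returned id set.
    """
    if n_missing + n_discrepancy + n_poor > n_total:
        raise ValueError("verdict-class counts exceed corpus size")
    rng = np.random.default_rng(seed)
    verdicts = (["MISSING_FORM"] * n_missing
                + ["DISCREPANCY_FORM"] * n_discrepancy
                + ["POOR_SCAN"] * n_poor
                + ["OK"] * (n_total - n_missing - n_discrepancy - n_poor))
    order = rng.permutation(n_total)
    spec = GenSpec(
        seed=seed,
        pages_min=1,
        pages_max=1,
        plant_rates=PlantRates(qc_table=0.0, handwriting_line=0.0,
                               header_line=0.0),
        body_lines_min=3,
        body_lines_max=5,
    )
    docs: list[OcrDocument] = []
    truths: list[GroundTruth] = []
    poor_ids: set[str] = set()
    counter = 0

    for i in order:
        verdict = verdicts[i]
        report_id = f"TCGA-SYN-{counter:05d}"
        lid = [0]

        def next_id() -> str:
            lid[0] += 1
            return f"{report_id}-L{lid[0]:04d}"

        if verdict == "MISSING_FORM":
            page, pt = _banner_page(1, MISSING_FORM_PHRASE, next_id)
        elif verdict == "DISCREPANCY_FORM":
            page, pt = _banner_page(1, DISCREPANCY_FORM_PHRASE, next_id)
        else:
            page, pt = _content_page(
                np.random.default_rng([seed, counter]), spec, label, 1, next_id
            )
        doc = OcrDocument(report_id, (page,))
        if verdict == "POOR_SCAN":
            poor_ids.add(report_id)
        docs.append(doc)
        truths.append(GroundTruth(report_id=report_id, verdict=verdict,
                                  pages=[pt]))
        counter += 1
    return docs, poor_ids, truths
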