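"""Whole-report exclusion by page-level phrase scan.

Some scanned reports are not pathology reports at all: placeholder forms
stating that the pathology report is missing, and discrepancy forms filed
when the recorded diagnosis was disputed. Both carry a fixed banner phrase
that survives OCR well enough for fuzzy detection. A third category --
reports whose scan quality is too poor to use -- has no computable
signature, so it is supplied as an explicit exclusion list; a low mean
word confidence raises an advisory flag for triage but never removes a
report on its own.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .blocks import OcrDocument
from .fuzzy import KeywordSpec, fuzzy_find

MISSING_FORM_PHRASE = "TCGA Missing Pathology Report Form"
DISCREPANCY_FORM_PHRASE = "TCGA Pathologic Diagnosis Discrepancy Form"

#: Default fuzzy allowance for the two banner phrases: they are long, so a
#: couple of OCR character errors are tolerated without risking collision
#: with ordinary diagnostic text.
DEFAULT_PHRASE_ALLOWANCE = 2

DEFAULT_MISSING_SPEC = KeywordSpec(MISSING_FORM_PHRASE, DEFAULT_PHRASE_ALLOWANCE)
DEFAULT_DISCREPANCY_SPEC = KeywordSpec(DISCREPANCY_FORM_PHRASE, DEFAULT_PHRASE_ALLOWANCE)


class Verdict(str, enum.Enum):
    OK = "OK"
    MISSING_FORM = "MISSING_FORM"
    DISCREPANCY_FORM = "DISCREPANCY_FORM"
    POOR_SCAN = "POOR_SCAN"


@dataclass(frozen=True)
class ScreenVerdict:
    report_id: str
    verdict: Verdict
    matched_phrase: Optional[str] = None
    page_number: Optional[int] = None
    low_confidence_flag: bool = False

    def __post_init__(self) -> None:
        if self.verdict in (Verdict.MISSING_FORM, Verdict.DISCREPANCY_FORM):
            if self.matched_phrase is None or self.page_number is None:
                raise ValueError(f"{self.verdict} verdict requires evidence")


def _mean_confidence(doc: OcrDocument) -> Optional[float]:
    vals = [
        w.confidence
        for page in doc.pages
        for line in page.lines
        for w in line.words
        if w.confidence is not None
    ]
    if not vals:
        return None
    return sum(vals) / len(vals)


def screen_report(
    doc: OcrDocument,
    missing_spec: KeywordSpec = DEFAULT_MISSING_SPEC,
    discrepancy_spec: KeywordSpec = DEFAULT_DISCREPANCY_SPEC,
    poor_scan_ids: Iterable[str] = (),
    confidence_floor: float = 50.0,
) -> ScreenVerdict:
    """Classify one report: missing-form, discrepancy-form, poor-scan, or OK.

    The missing-pathology phrase takes precedence over the discrepancy
    phrase; both are searched within each page's concatenated line text.
    """
    poor = set(poor_scan_ids)
    mean_conf = _mean_confidence(doc)
    low_conf = mean_conf is not None and mean_conf < confidence_floor

    for spec, verdict in (
        (missing_spec, Verdict.MISSING_FORM),
        (discrepancy_spec, Verdict.DISCREPANCY_FORM),
    ):
        for page in doc.pages:
            if fuzzy_find(page.text, spec):
                return ScreenVerdict(
                    report_id=doc.report_id,
                    verdict=verdict,
                    matched_phrase=spec.phrase,
                    page_number=page.page_number,
                    low_confidence_flag=low_conf,
                )
    if doc.report_id in poor:
        return ScreenVerdict(doc.report_id, Verdict.POOR_SCAN,
                             low_confidence_flag=low_conf)
    return ScreenVerdict(doc.report_id, Verdict.OK, low_confidence_flag=low_conf)


def screen_corpus(
    docs: Sequence[OcrDocument],
    missing_spec: KeywordSpec = DEFAULT_MISSING_SPEC,
    discrepancy_spec: KeywordSpec = DEFAULT_DISCREPANCY_SPEC,
    poor_scan_ids: Iterable[str] = (),
) -> tuple[list[OcrDocument], list[ScreenVerdict]]:
    """Screen every document; return (kept documents, all verdicts).

    Raises on duplicate report ids: the pipeline guarantees one report per
    patient, and silently screening duplicates would corrupt the counts.
    """
    seen: set[str] = set()
    for doc in docs:
        if doc.report_id in seen:
            raise ValueError(f"duplicate report_id {doc.report_id!r} in corpus")
        seen.add(doc.report_id)

    poor = set(poor_scan_ids)
    kept: list[OcrDocument] = []
    verdicts: list[ScreenVerdict] = []
    for doc in docs:
        v = screen_report(doc, missing_spec, discrepancy_spec, poor)
        verdicts.append(v)
        if v.verdict is Verdict.OK:
            kept.append(doc)
    return kept, verdicts


def verdict_counts(verdicts: Sequence[ScreenVerdict]) -> dict[str, int]:
    counts = {v.value: 0 for v in Verdict}
    for v in verdicts:
        counts[v.verdict.value] += 1
    return counts
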