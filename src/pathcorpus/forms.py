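"""Detection and removal of multiple-choice (synoptic) form reports.

Form pages list every answer option for each question; because OCR cannot
tell which option was ticked, the extracted text is unlearnable and must
go. Detection is a two-stage funnel:

1. a *structural* screen on layout statistics (tables per report,
   selection elements per report, mean and max selection elements per
   page) -- sensitive but unspecific;
2. a *keyword* screen on disease-specific phrases drawn from form question
   and answer text, fuzzy-matched, requiring a minimum number of distinct
   keyword hits -- this restores specificity.

Every flagged report carries ``needs_review=True``: the automatic decision
is a proposal, and a review roster of human decisions has the final word.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .blocks import OcrDocument, Page
from .fuzzy import KeywordSpec, fuzzy_find

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StructuralThresholds:
    """A report exceeding ANY threshold becomes a form candidate.

    Defaults are deliberately conservative starting points; they are
    expected to be tuned per dataset (the distributions of tables and
    checkboxes differ between scanning pipelines).
    """

    max_tables_per_report: int = 3
    max_sel_elements_per_report: int = 10
    max_mean_sel_per_page: float = 4.0
    max_max_sel_per_page: int = 8

    def __post_init__(self) -> None:
        if min(self.max_tables_per_report, self.max_sel_elements_per_report,
               self.max_mean_sel_per_page, self.max_max_sel_per_page) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class StructuralStats:
    n_tables: int
    n_sel_elements: int
    mean_sel_per_page: float
    max_sel_per_page: int


@dataclass(frozen=True)
class FormFilterSpec:
    """Disease-specific keyword filter: flag when >= min_matches distinct
    keywords fuzzy-match anywhere in the report."""

    disease_label: str
    keywords: tuple[KeywordSpec, ...]
    min_matches: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.min_matches <= len(self.keywords):
            raise ValueError(
                f"min_matches must be in [1, {len(self.keywords)}], "
                f"got {self.min_matches}"
            )


class FormDecision(str, enum.Enum):
    KEEP = "KEEP"
    DROP_REPORT = "DROP_REPORT"
    DROP_PAGES = "DROP_PAGES"


@dataclass(frozen=True)
class PageFormRule:
    """A page counts as a form page when it holds >= min_sel selection
    elements or any form keyword hits it."""

    min_sel: int = 5


@dataclass
class FormVerdict:
    report_id: str
    candidate: bool
    flagged: bool
    matched_keywords: list[str] = field(default_factory=list)
    decision: FormDecision = FormDecision.KEEP
    dropped_pages: list[int] = field(default_factory=list)
    needs_review: bool = False
    stats: Optional[StructuralStats] = None

    def __post_init__(self) -> None:
        if self.decision is FormDecision.DROP_PAGES and not self.dropped_pages:
            raise ValueError("DROP_PAGES verdict requires dropped pages")


# The colon-cancer form keyword set (printed in full in the source study);
# forms for this disease are question/answer lists whose phrases almost
# never occur in free-text diagnostic prose.
COLON_FORM_FILTER = FormFilterSpec(
    disease_label="COAD",
    keywords=(
        KeywordSpec("signet ring feature:", 1),
        KeywordSpec("histologic heterogeneity:", 1),
        KeywordSpec("Crohn's like reaction", 1),
        KeywordSpec("plasma cell rich stroma", 1),
        KeywordSpec("angiolymphatic invasion:", 1),
        KeywordSpec("Garland necrosis present:", 1),
        KeywordSpec("TIL cells/HPF", 1),
        KeywordSpec("pathologist comment:", 1),
    ),
    min_matches=2,
)

# Liver and cervix form filters ship as extensible stubs: only the seed
# phrases are public, the full lists (14 and 21 keywords) are not. Users
# extend these via configuration; min_matches=2 mirrors the colon rule.
LIVER_FORM_FILTER_STUB = FormFilterSpec(
    disease_label="LIHC",
    keywords=(
        KeywordSpec("hepatitis (specify type)", 1),
        KeywordSpec("(check all that apply)", 1),
    ),
    min_matches=2,
)
CERVIX_FORM_FILTER_STUB = FormFilterSpec(
    disease_label="CESC",
    keywords=(
        KeywordSpec("(check all that apply)", 1),
    ),
    min_matches=1,
)


def structural_screen(
    doc: OcrDocument,
    thresholds: StructuralThresholds = StructuralThresholds(),
) -> tuple[bool, StructuralStats]:
    """First-stage filter on layout statistics. Candidate iff any statistic
    exceeds its threshold (strictly)."""
    per_page = [len(p.selection_elements) for p in doc.pages]
    stats = StructuralStats(
        n_tables=sum(len(p.tables) for p in doc.pages),
        n_sel_elements=sum(per_page),
        mean_sel_per_page=sum(per_page) / len(per_page),
        max_sel_per_page=max(per_page),
    )
    candidate = (
        stats.n_tables > thresholds.max_tables_per_report
        or stats.n_sel_elements > thresholds.max_sel_elements_per_report
        or stats.mean_sel_per_page > thresholds.max_mean_sel_per_page
        or stats.max_sel_per_page > thresholds.max_max_sel_per_page
    )
    return candidate, stats


def keyword_screen(
    doc: OcrDocument, spec: FormFilterSpec
) -> tuple[bool, list[str]]:
    """Second-stage filter: count DISTINCT keywords with at least one fuzzy
    match anywhere in the report."""
    full_text = " ".join(page.text for page in doc.pages)
    matched = [kw.phrase for kw in spec.keywords if fuzzy_find(full_text, kw)]
    return len(matched) >= spec.min_matches, matched


def _is_form_page(page: Page, spec: FormFilterSpec, rule: PageFormRule) -> bool:
    if len(page.selection_elements) >= rule.min_sel:
        return True
    text = page.text
    return any(fuzzy_find(text, kw) for kw in spec.keywords)


def decide_form_action(
    doc: OcrDocument,
    candidate: bool,
    flagged: bool,
    spec: FormFilterSpec,
    page_rule: PageFormRule = PageFormRule(),
    mode: str = "and",
    matched_keywords: Optional[Sequence[str]] = None,
    stats: Optional[StructuralStats] = None,
) -> FormVerdict:
    """Turn the two screen outcomes into a removal proposal.

    ``mode='and'`` (default) triggers only when both screens fire,
    mirroring the two-stage funnel; ``mode='or'`` trades specificity for
    recall. When triggered, pages that look form-like (checkbox-dense or
    keyword-hit) are proposed for removal; if every page qualifies the
    whole report is dropped. All triggered verdicts need human review.
    """
    if mode not in ("and", "or"):
        raise ValueError(f"mode must be 'and' or 'or', got {mode!r}")
    triggered = (candidate and flagged) if mode == "and" else (candidate or flagged)
    verdict = FormVerdict(
        report_id=doc.report_id,
        candidate=candidate,
        flagged=flagged,
        matched_keywords=list(matched_keywords or []),
        stats=stats,
    )
    if not triggered:
        return verdict
    form_pages = [
        p.page_number for p in doc.pages if _is_form_page(p, spec, page_rule)
    ]
    verdict.needs_review = True
    if form_pages and len(form_pages) == len(doc.pages):
        verdict.decision = FormDecision.DROP_REPORT
    elif form_pages:
        verdict.decision = FormDecision.DROP_PAGES
        verdict.dropped_pages = form_pages
    return verdict


def screen_for_forms(
    doc: OcrDocument,
    spec: FormFilterSpec,
    thresholds: StructuralThresholds = StructuralThresholds(),
    page_rule: PageFormRule = PageFormRule(),
    mode: str = "and",
) -> FormVerdict:
    """Run both screens and the decision rule on one document."""
    candidate, stats = structural_screen(doc, thresholds)
    flagged, matched = keyword_screen(doc, spec)
    return decide_form_action(
        doc, candidate, flagged, spec, page_rule, mode,
        matched_keywords=matched, stats=stats,
    )


def apply_review_roster(
    verdicts: Sequence[FormVerdict],
    roster: Mapping[str, FormDecision],
) -> list[FormVerdict]:
    """Apply human review decisions; roster entries override and clear the
    needs_review flag. Roster ids absent from the verdict list are warned
    about and ignored."""
    by_id = {v.report_id: v for v in verdicts}
    for rid in roster:
        if rid not in by_id:
            logger.warning("roster id %r matches no verdict; ignored", rid)
    out: list[FormVerdict] = []
    for v in verdicts:
        if v.report_id in roster:
            decision = roster[v.report_id]
            out.append(
                FormVerdict(
                    report_id=v.report_id,
                    candidate=v.candidate,
                    flagged=v.flagged,
                    matched_keywords=list(v.matched_keywords),
                    decision=decision,
                    dropped_pages=(
                        list(v.dropped_pages)
                        if decision is FormDecision.DROP_PAGES else []
                    ),
                    needs_review=False,
                    stats=v.stats,
                )
            )
        else:
            out.append(v)
    return out


def apply_form_verdict(doc: OcrDocument, verdict: FormVerdict) -> Optional[OcrDocument]:
    """Materialize a verdict: None for DROP_REPORT, page-filtered document
    for DROP_PAGES, unchanged document for KEEP."""
    if verdict.decision is FormDecision.DROP_REPORT:
        return None
    if verdict.decision is FormDecision.DROP_PAGES:
        dropped = set(verdict.dropped_pages)
        pages = tuple(p for p in doc.pages if p.page_number not in dropped)
        if not pages:
            return None
        return OcrDocument(report_id=doc.report_id, pages=pages)
    return doc
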