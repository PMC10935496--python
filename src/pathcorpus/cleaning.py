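"""Final line-level cleaning, report assembly, and corpus export.

Two line filters run after table removal: (1) lines consisting entirely of
handwriting-annotated words are dropped -- handwritten marks were added
during data collection, are not part of the clinical report, and OCR
mangles them anyway; (2) lines matching any of a configured list of
regular expressions are dropped -- these target clinic headers, fax
banners, page footers and similar boilerplate that would otherwise leak
site identity into the text. Surviving lines are joined with period
delimiters within a page and pages are joined with spaces, yielding one
text string per patient which is exported with its cancer-type label.

Every stage logs counts into an :class:`AuditLog` whose conservation
invariant (items_in - items_removed = items_out) is enforced on entry.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .blocks import Line, OcrDocument, Page
from .cases import SelectionOutcome

SHORT_REPORT = "SHORT_REPORT"
NEEDS_REVIEW = "NEEDS_REVIEW"


class ConfigError(ValueError):
    """Invalid cleaning configuration (e.g. a non-compiling pattern)."""


@dataclass
class CleaningConfig:
    """Regex removal list plus assembly parameters.

    Patterns use *search* semantics (a match anywhere in the line removes
    it) and are case-insensitive by default: the boilerplate they target
    is frequently re-cased by OCR.
    """

    regexes: Sequence[str] = ()
    case_sensitive: bool = False
    short_report_max_lines: int = 5
    line_delimiter: str = ". "
    page_delimiter: str = " "

    def __post_init__(self) -> None:
        flags = 0 if self.case_sensitive else re.IGNORECASE
        compiled = []
        for pat in self.regexes:
            try:
                compiled.append(re.compile(pat, flags))
            except re.error as exc:
                raise ConfigError(f"regex does not compile: {pat!r} ({exc})") from exc
        self._compiled = compiled

    @property
    def compiled(self) -> list[re.Pattern]:
        return self._compiled


@dataclass
class StageCounts:
    items_in: int
    items_removed: int
    per_rule: dict[str, int] = field(default_factory=dict)

    @property
    def items_out(self) -> int:
        return self.items_in - self.items_removed

    def __post_init__(self) -> None:
        if self.items_removed > self.items_in or self.items_removed < 0:
            raise ValueError(
                f"removed {self.items_removed} of {self.items_in} items"
            )


@dataclass
class AuditLog:
    stages: dict[str, StageCounts] = field(default_factory=dict)

    def record(self, stage: str, items_in: int, items_removed: int,
               per_rule: Optional[Mapping[str, int]] = None) -> None:
        counts = StageCounts(items_in, items_removed, dict(per_rule or {}))
        if stage in self.stages:
            prev = self.stages[stage]
            merged_rules = dict(prev.per_rule)
            for k, v in counts.per_rule.items():
                merged_rules[k] = merged_rules.get(k, 0) + v
            self.stages[stage] = StageCounts(
                prev.items_in + counts.items_in,
                prev.items_removed + counts.items_removed,
                merged_rules,
            )
        else:
            self.stages[stage] = counts

    def to_dict(self) -> dict:
        return {
            name: {
                "items_in": c.items_in,
                "items_removed": c.items_removed,
                "items_out": c.items_out,
                "per_rule": c.per_rule,
            }
            for name, c in self.stages.items()
        }


@dataclass(frozen=True)
class CorpusRecord:
    """One patient's assembled report text with its ground-truth label."""

    patient_id: str
    project_label: str
    text: str
    n_pages: int = 0
    n_lines: int = 0
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.text and not self.flags:
            raise ValueError(
                f"{self.patient_id}: empty text requires an explanatory flag"
            )


def remove_handwritten_lines(page: Page) -> tuple[Page, list[Line]]:
    """Drop lines whose words are all HANDWRITING (and non-empty).

    Mixed printed/handwritten lines are kept: the rule is "entirely
    handwritten". Word-less lines cannot satisfy it and pass through.
    """
    kept = [l for l in page.lines if not l.is_handwritten_only]
    removed = [l for l in page.lines if l.is_handwritten_only]
    return (
        Page(page.page_number, tuple(kept), page.tables, page.selection_elements),
        removed,
    )


def remove_matched_lines(
    page: Page, config: CleaningConfig
) -> tuple[Page, list[tuple[Line, int]]]:
    """Drop lines in which ANY configured pattern finds a match; the first
    matching pattern's index is recorded for the audit."""
    kept: list[Line] = []
    removed: list[tuple[Line, int]] = []
    for line in page.lines:
        hit = None
        for idx, pat in enumerate(config.compiled):
            if pat.search(line.text):
                hit = idx
                break
        if hit is None:
            kept.append(line)
        else:
            removed.append((line, hit))
    return (
        Page(page.page_number, tuple(kept), page.tables, page.selection_elements),
        removed,
    )


def flag_short_reports(doc: OcrDocument, max_lines: int = 5) -> frozenset[str]:
    """Flag (never remove) suspiciously short reports.

    Short reports are frequently legitimate -- terse but clinically
    complete -- so they are surfaced for review rather than dropped. A
    zero-line report additionally gets NEEDS_REVIEW.
    """
    n = doc.n_lines
    flags: set[str] = set()
    if n <= max_lines:
        flags.add(SHORT_REPORT)
    if n == 0:
        flags.add(NEEDS_REVIEW)
    return frozenset(flags)


def assemble_text(doc: OcrDocument, config: CleaningConfig = CleaningConfig()) -> str:
    """Join lines within a page by the line delimiter and pages by the page
    delimiter; no leading/trailing delimiter; empty pages contribute
    nothing."""
    page_texts = [
        config.line_delimiter.join(l.text for l in page.lines)
        for page in doc.pages
        if page.lines
    ]
    return config.page_delimiter.join(page_texts)


def clean_document(
    doc: OcrDocument,
    config: CleaningConfig = CleaningConfig(),
    audit: Optional[AuditLog] = None,
) -> OcrDocument:
    """Run handwriting removal then regex removal over every page."""
    audit = audit if audit is not None else AuditLog()
    pages: list[Page] = []
    hw_in = hw_removed = 0
    rx_in = rx_removed = 0
    rule_counts: dict[str, int] = {}
    for page in doc.pages:
        hw_in += len(page.lines)
        page, removed_hw = remove_handwritten_lines(page)
        hw_removed += len(removed_hw)
        rx_in += len(page.lines)
        page, removed_rx = remove_matched_lines(page, config)
        rx_removed += len(removed_rx)
        for _, idx in removed_rx:
            key = f"pattern_{idx}"
            rule_counts[key] = rule_counts.get(key, 0) + 1
        pages.append(page)
    audit.record("handwriting_removal", hw_in, hw_removed)
    audit.record("regex_removal", rx_in, rx_removed, rule_counts)
    return OcrDocument(report_id=doc.report_id, pages=tuple(pages))


def build_corpus(
    docs: Sequence[OcrDocument],
    selection: SelectionOutcome,
    labels: Mapping[str, str],
    config: CleaningConfig = CleaningConfig(),
) -> tuple[list[CorpusRecord], AuditLog]:
    """Assemble one labeled record per kept patient that has a document.

    Kept patients missing a document or a label are excluded and listed in
    the audit; documents for non-kept patients are ignored.
    """
    audit = AuditLog()
    by_id = {d.report_id: d for d in docs}
    records: list[CorpusRecord] = []
    missing_doc: list[str] = []
    missing_label: list[str] = []
    for pid in selection.kept:
        doc = by_id.get(pid)
        if doc is None:
            missing_doc.append(pid)
            continue
        label = labels.get(pid)
        if label is None:
            missing_label.append(pid)
            continue
        flags = flag_short_reports(doc, config.short_report_max_lines)
        records.append(
            CorpusRecord(
                patient_id=pid,
                project_label=label,
                text=assemble_text(doc, config),
                n_pages=len(doc.pages),
                n_lines=doc.n_lines,
                flags=flags,
            )
        )
    audit.record(
        "corpus_assembly",
        items_in=len(selection.kept),
        items_removed=len(missing_doc) + len(missing_label),
        per_rule={"missing_document": len(missing_doc),
                  "missing_label": len(missing_label)},
    )
    return records, audit


def summarize_corpus(records: Sequence[CorpusRecord]) -> pd.DataFrame:
    """Per-label corpus statistics, ordered by prevalence (descending)."""
    if not records:
        return pd.DataFrame(
            columns=["project_label", "n_patients", "mean_pages", "mean_lines"]
        )
    df = pd.DataFrame(
        {
            "project_label": [r.project_label for r in records],
            "n_pages": [r.n_pages for r in records],
            "n_lines": [r.n_lines for r in records],
        }
    )
    out = (
        df.groupby("project_label")
        .agg(n_patients=("project_label", "size"),
             mean_pages=("n_pages", "mean"),
             mean_lines=("n_lines", "mean"))
        .reset_index()
        .sort_values(["n_patients", "project_label"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return out


# ---------------------------------------------------------------------------
# corpus serialization

def write_corpus_jsonl(records: Sequence[CorpusRecord], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps({
                "patient_id": r.patient_id,
                "project_label": r.project_label,
                "text": r.text,
                "n_pages": r.n_pages,
                "n_lines": r.n_lines,
                "flags": sorted(r.flags),
            }, sort_keys=True) + "\n")


def read_corpus_jsonl(path: Union[str, Path]) -> list[CorpusRecord]:
    records: list[CorpusRecord] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            records.append(
                CorpusRecord(
                    patient_id=obj["patient_id"],
                    project_label=obj["project_label"],
                    text=obj["text"],
                    n_pages=obj.get("n_pages", 0),
                    n_lines=obj.get("n_lines", 0),
                    flags=frozenset(obj.get("flags", [])),
                )
            )
    return records


def write_corpus_tsv(records: Sequence[CorpusRecord], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "project_label": [r.project_label for r in records],
            "text": [r.text for r in records],
            "flags": [",".join(sorted(r.flags)) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_regex_file(path: Union[str, Path]) -> list[str]:
    """Read a pattern list: one regex per line, '#' comments and blanks
    skipped."""
    patterns: list[str] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            patterns.append(line)
    return patterns


def example_cleaning_regexes() -> list[str]:
    """The bundled example pattern list (clinic headers, fax banners, page
    footers). Real deployments supply their own, typically much longer,
    list tuned to their report set."""
    from importlib.resources import files

    return load_regex_file(files("pathcorpus.data") / "example_cleaning_regexes.txt")
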