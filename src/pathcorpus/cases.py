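"""Patient-level case selection from biospecimen and outcomes metadata.

Selection keeps a patient only when (1) they have exactly one associated
pathology report, (2) the reported sample is a primary tumor, and (3) a
survival time exists for them in the outcomes resource. Exclusion reasons
are recorded in that order -- a patient qualifying for several reasons is
booked under the first -- so the audit counts are reproducible and the
kept set is unaffected by the ordering.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

PRIMARY_TUMOR = "primary tumor"


class RemovalReason(str, enum.Enum):
    NO_REPORT = "NO_REPORT"
    MULTIPLE_REPORTS = "MULTIPLE_REPORTS"
    NON_PRIMARY = "NON_PRIMARY"
    NO_CDR_SURVIVAL = "NO_CDR_SURVIVAL"


@dataclass(frozen=True)
class CaseRecord:
    """One biospecimen sample row joined with outcome availability."""

    patient_id: str
    sample_type: str
    report_uuid: Optional[str] = None
    has_survival: bool = False
    project_label: Optional[str] = None
    demographics: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")


@dataclass
class SelectionOutcome:
    kept: list[str] = field(default_factory=list)
    removed: dict[str, RemovalReason] = field(default_factory=dict)

    @property
    def reason_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for reason in self.removed.values():
            counts[reason.value] = counts.get(reason.value, 0) + 1
        return counts

    def to_audit_dict(self) -> dict:
        return {
            "n_kept": len(self.kept),
            "n_removed": len(self.removed),
            "reason_counts": self.reason_counts,
            "removed": {pid: r.value for pid, r in sorted(self.removed.items())},
        }


def _is_primary(sample_type: str) -> bool:
    # exact match after trimming/folding, so variants like
    # "Primary Tumor Metastasis" are not silently accepted
    return sample_type.strip().casefold() == PRIMARY_TUMOR


def select_cases(records: Sequence[CaseRecord]) -> SelectionOutcome:
    """Apply the patient-level exclusion rules and return kept/removed sets.

    Rules, in precedence order: no report, multiple distinct reports,
    non-primary tumor sample, no survival outcome. The result is a pure
    function of the record *set*: input order never changes it.
    """
    by_patient: dict[str, list[CaseRecord]] = {}
    seen_pairs: set[tuple[str, Optional[str]]] = set()
    dup_rows = 0
    for rec in records:
        key = (rec.patient_id, rec.report_uuid)
        if rec.report_uuid is not None and key in seen_pairs:
            dup_rows += 1
            continue
        seen_pairs.add(key)
        by_patient.setdefault(rec.patient_id, []).append(rec)
    if dup_rows:
        logger.warning("collapsed %d duplicate (patient, report) rows", dup_rows)

    outcome = SelectionOutcome()
    for pid in sorted(by_patient):
        recs = by_patient[pid]
        report_uuids = {r.report_uuid for r in recs if r.report_uuid}
        if not report_uuids:
            outcome.removed[pid] = RemovalReason.NO_REPORT
            continue
        if len(report_uuids) > 1:
            outcome.removed[pid] = RemovalReason.MULTIPLE_REPORTS
            continue
        reported = [r for r in recs if r.report_uuid]
        if not any(_is_primary(r.sample_type) for r in reported):
            outcome.removed[pid] = RemovalReason.NON_PRIMARY
            continue
        if not any(r.has_survival for r in recs):
            outcome.removed[pid] = RemovalReason.NO_CDR_SURVIVAL
            continue
        outcome.kept.append(pid)
    return outcome


DEFAULT_SAMPLE_COLUMNS = {
    "patient_id": "patient_id",
    "sample_type": "sample_type",
    "report_uuid": "pathology_report_uuid",
}
DEFAULT_OUTCOME_COLUMNS = {
    "patient_id": "patient_id",
    "survival_time": "survival_time",
}


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


def read_case_tables(
    sample_path: Union[str, Path],
    outcomes_path: Union[str, Path],
    sample_columns: Optional[Mapping[str, str]] = None,
    outcome_columns: Optional[Mapping[str, str]] = None,
) -> list[CaseRecord]:
    """Join the biospecimen sample table with the outcomes table.

    Both inputs are tab-delimited with a header row. ``has_survival`` is
    true iff the patient appears in the outcomes table with a non-missing
    survival time. Column names are remappable through the ``*_columns``
    maps (logical name -> actual header).
    """
    scols = dict(DEFAULT_SAMPLE_COLUMNS)
    scols.update(sample_columns or {})
    ocols = dict(DEFAULT_OUTCOME_COLUMNS)
    ocols.update(outcome_columns or {})

    samples = pd.read_csv(sample_path, sep="\t", dtype=str)
    outcomes = pd.read_csv(outcomes_path, sep="\t", dtype=str)
    for logical, actual in scols.items():
        if actual not in samples.columns:
            raise SchemaError(f"sample table missing column {actual!r} ({logical})")
    for logical, actual in ocols.items():
        if actual not in outcomes.columns:
            raise SchemaError(f"outcomes table missing column {actual!r} ({logical})")

    surv = outcomes[ocols["survival_time"]].notna() & (
        outcomes[ocols["survival_time"]].str.strip() != ""
    )
    with_survival = set(outcomes.loc[surv, ocols["patient_id"]])

    project_col = samples["project_label"] if "project_label" in samples.columns else None

    records: list[CaseRecord] = []
    for idx, row in samples.iterrows():
        uuid = row[scols["report_uuid"]]
        if pd.isna(uuid) or not str(uuid).strip():
            uuid = None
        else:
            uuid = str(uuid).strip()
        pid = str(row[scols["patient_id"]])
        records.append(
            CaseRecord(
                patient_id=pid,
                sample_type=str(row[scols["sample_type"]] or ""),
                report_uuid=uuid,
                has_survival=pid in with_survival,
                project_label=(
                    str(project_col.loc[idx]) if project_col is not None
                    and pd.notna(project_col.loc[idx]) else None
                ),
            )
        )
    return records
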