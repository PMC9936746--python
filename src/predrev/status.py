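"""Completeness flags for CHARMS domains, records, and PROBAST assessments.

A CHARMS domain is complete when every required cell in it is filled — a
cell holding the explicit "No information" marker counts as filled, an
empty cell does not.  Participant characteristics belong to the
participants domain.  The record-level flag is the conjunction of the
eleven domain flags and carries the summary-sheet status message.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reporting import ReportTable
from .schema import (
    APPLICABILITY_DOMAINS,
    CharmsDomain,
    ModelRecord,
    ProbastDomain,
    ReviewProject,
)

COMPLETE_MESSAGE = "All information has been successfully registered"
INCOMPLETE_MESSAGE = "Incomplete data extraction"


@dataclass(frozen=True)
class DomainStatus:
    domain: CharmsDomain
    complete: bool
    missing_keys: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.complete == (not self.missing_keys)


@dataclass(frozen=True)
class RecordStatus:
    charms_complete: bool
    probast_complete: bool
    message: str


def charms_domain_status(
    project: ReviewProject, record: ModelRecord, domain: CharmsDomain
) -> DomainStatus:
    """Complete iff every required cell of the domain is filled.

    For the participants domain the review-specific participant
    characteristics are part of the domain.
    """
    missing: list[str] = []
    for spec in project.field_catalog:
        if spec.domain is domain and spec.required:
            v = record.charms.values.get(spec.key)
            if v is None or not v.filled:
                missing.append(spec.key)
    if domain is CharmsDomain.PARTICIPANTS:
        for cspec in project.characteristic_specs:
            v = record.charms.participant_values.get(cspec.key)
            if v is None or not v.filled:
                missing.append(cspec.key)
    return DomainStatus(domain=domain, complete=not missing, missing_keys=tuple(missing))


def charms_status(project: ReviewProject, record: ModelRecord) -> RecordStatus:
    """Record-level flag: complete iff all eleven domains are complete."""
    complete = all(
        charms_domain_status(project, record, d).complete for d in CharmsDomain
    )
    return RecordStatus(
        charms_complete=complete,
        probast_complete=probast_status(record),
        message=COMPLETE_MESSAGE if complete else INCOMPLETE_MESSAGE,
    )


def probast_status(record: ModelRecord) -> bool:
    """True iff all four RoB ratings, all three applicability ratings and
    both overall judgments are present."""
    pa = record.probast
    if any(pa.rob.get(d) is None for d in ProbastDomain):
        return False
    if any(pa.applicability.get(d) is None for d in APPLICABILITY_DOMAINS):
        return False
    return pa.overall_rob is not None and pa.overall_applicability is not None


def summary_rows(project: ReviewProject) -> ReportTable:
    """The summary-sheet view: one row per model with both status flags."""
    header = ["Model ID", "Author", "Year", "Identifier", "Journal",
              "Model name", "CHARMS status", "PROBAST status"]
    rows = []
    for rec in project.models:
        st = charms_status(project, rec)
        rows.append([
            rec.study.model_id,
            rec.study.author,
            str(rec.study.year),
            rec.study.identifier,
            rec.study.journal,
            rec.study.model_name,
            st.message,
            "Complete" if st.probast_complete else "Incomplete",
        ])
    return ReportTable(title="Summary", header=header, rows=rows)
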