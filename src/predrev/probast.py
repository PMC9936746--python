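"""PROBAST assessment mechanics.

Each of the four domains (participants, predictors, outcome, analysis)
carries a fixed set of signalling questions answered on a five-point scale
(yes / probably yes / probably no / no / no information).  Once — and only
while — every signalling question of a domain is answered, the domain's
risk-of-bias rating (and, outside the analysis domain, its applicability
rating) can be recorded as low / high / unclear.

Overall judgments follow the standard worst-rating rule: a single high
domain makes the overall judgment high; otherwise a single unclear domain
makes it unclear; otherwise it is low.  They are recomputed automatically
whenever ratings change, unless the reviewer has set a manual override.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .schema import (
    APPLICABILITY_DOMAINS,
    Answer,
    CharmsRecord,
    FieldState,
    Judgment,
    ModelRecord,
    ProbastDomain,
    ValidationError,
)

# context rows transferred from the extraction record, in display order
_CONTEXT_FIELDS = (
    ("Source of data", "source_of_data"),
    ("Inclusion criteria", "inclusion_criteria"),
    ("Exclusion criteria", "exclusion_criteria"),
    ("Outcome definition", "outcome_definition"),
    ("Internal validation", "internal_validation"),
    ("External validation", "external_validation"),
    ("Discrimination measures", "discrimination"),
    ("Calibration measures", "calibration"),
)

CONTEXT_PLACEHOLDER = "(not extracted)"


def build_context(charms: CharmsRecord) -> dict[str, str]:
    """Extraction excerpts shown alongside the assessment form.

    Deterministic, read-only derivation: the same record always yields the
    same mapping.  Cells never filled in render as an explicit placeholder
    so the assessor can tell "not extracted" from "study reports nothing".
    """
    ctx: dict[str, str] = {}
    for label, key in _CONTEXT_FIELDS:
        v = charms.values.get(key)
        if v is None or v.state is FieldState.EMPTY:
            ctx[label] = CONTEXT_PLACEHOLDER
        else:
            ctx[label] = v.render()
    return ctx


def domain_answered(record: ModelRecord, domain: ProbastDomain) -> bool:
    return all(a is not None for a in record.probast.answers[domain])


def can_rate(record: ModelRecord, domain: ProbastDomain) -> bool:
    """The editability gate: true iff every signalling answer is present."""
    return domain_answered(record, domain)


def answer_signalling(
    record: ModelRecord,
    domain: ProbastDomain,
    index: int,
    answer: Optional[Answer],
) -> ModelRecord:
    """Store (or, with ``None``, clear) one signalling answer.

    Clearing an answer of a fully-answered domain closes the gate, so the
    domain's ratings — and consequently the overall judgments — are cleared
    too, never left dangling above incomplete answers.
    """
    slots = record.probast.answers[domain]
    if not 0 <= index < len(slots):
        raise ValidationError(
            f"{domain.value} has {len(slots)} signalling questions; "
            f"index {index} out of range")
    was_complete = domain_answered(record, domain)
    slots[index] = answer
    if was_complete and not domain_answered(record, domain):
        record.probast.rob[domain] = None
        if domain.has_applicability:
            record.probast.applicability[domain] = None
        _refresh_overall(record)
    return record


def rate(
    record: ModelRecord,
    domain: ProbastDomain,
    rob: Judgment,
    applicability: Optional[Judgment] = None,
) -> ModelRecord:
    """Record a domain's judgments; only allowed once the gate is open."""
    if not can_rate(record, domain):
        n_missing = sum(1 for a in record.probast.answers[domain] if a is None)
        raise ValidationError(
            f"cannot rate {domain.value}: {n_missing} signalling answer(s) missing")
    if domain.has_applicability:
        if applicability is None:
            raise ValidationError(f"{domain.value} requires an applicability judgment")
    elif applicability is not None:
        raise ValidationError("the analysis domain has no applicability assessment")
    record.probast.rob[domain] = rob
    if domain.has_applicability:
        record.probast.applicability[domain] = applicability
    _refresh_overall(record)
    return record


def aggregate(domain_judgments: Sequence[Judgment]) -> Judgment:
    """Worst-rating aggregation: HIGH if any HIGH, else UNCLEAR if any
    UNCLEAR, else LOW.  Equivalent to the maximum under the severity order
    LOW < UNCLEAR < HIGH."""
    js = list(domain_judgments)
    if not js or any(j is None for j in js):
        raise ValidationError("aggregate requires a non-empty, complete judgment list")
    if any(j is Judgment.HIGH for j in js):
        return Judgment.HIGH
    if any(j is Judgment.UNCLEAR for j in js):
        return Judgment.UNCLEAR
    return Judgment.LOW


def suggest_rating(answers: Iterable[Answer]) -> Judgment:
    """Advisory judgment from a domain's signalling answers (never auto-applied):
    any (probably) negative answer suggests high risk of bias; otherwise any
    missing information suggests unclear; all (probably) positive suggests low.
    """
    ans = list(answers)
    if not ans or any(a is None for a in ans):
        raise ValidationError("suggest_rating requires a complete answer list")
    if any(a in (Answer.NO, Answer.PROBABLY_NO) for a in ans):
        return Judgment.HIGH
    if any(a is Answer.NO_INFORMATION for a in ans):
        return Judgment.UNCLEAR
    return Judgment.LOW


def _refresh_overall(record: ModelRecord) -> None:
    """Recompute auto-derived overall judgments after any rating change."""
    pa = record.probast
    if not pa.overall_rob_override:
        robs = [pa.rob[d] for d in ProbastDomain]
        pa.overall_rob = aggregate(robs) if all(r is not None for r in robs) else None
    if not pa.overall_applicability_override:
        apps = [pa.applicability[d] for d in APPLICABILITY_DOMAINS]
        pa.overall_applicability = (
            aggregate(apps) if all(a is not None for a in apps) else None)


def override_overall(
    record: ModelRecord,
    overall_rob: Optional[Judgment] = None,
    overall_applicability: Optional[Judgment] = None,
) -> ModelRecord:
    """Manually pin one or both overall judgments; pass ``None`` to release
    an override and fall back to the automatic rule."""
    pa = record.probast
    if overall_rob is not None:
        pa.overall_rob = overall_rob
        pa.overall_rob_override = True
    else:
        pa.overall_rob_override = False
    if overall_applicability is not None:
        pa.overall_applicability = overall_applicability
        pa.overall_applicability_override = True
    else:
        pa.overall_applicability_override = False
    _refresh_overall(record)
    return record


def overall(record: ModelRecord) -> tuple[Judgment, Judgment]:
    """(overall risk of bias, overall applicability) for a fully rated model.

    Aggregated with the worst-rating rule, except that a manual override,
    when set, is returned instead.
    """
    pa = record.probast
    robs = [pa.rob.get(d) for d in ProbastDomain]
    apps = [pa.applicability.get(d) for d in APPLICABILITY_DOMAINS]
    if any(r is None for r in robs) or any(a is None for a in apps):
        raise ValidationError("overall judgment requires all domain ratings")
    rob = pa.overall_rob if pa.overall_rob_override else aggregate(robs)
    app = (pa.overall_applicability if pa.overall_applicability_override
           else aggregate(apps))
    return rob, app


def validation_warnings(project_catalog_record: ModelRecord) -> list[str]:
    """Advisory notes attached to an assessment.

    A development-only model (no external validation) judged low risk of
    bias overall gets a caution: without external validation, optimism in
    the reported performance cannot be ruled out.
    """
    rec = project_catalog_record
    warnings: list[str] = []
    ev = rec.charms.values.get("external_validation")
    try:
        rob, _ = overall(rec)
    except ValidationError:
        return warnings
    if rob is Judgment.LOW and ev is not None and \
            ev.state is FieldState.VALUE and ev.text == "No":
        warnings.append(
            "Overall risk of bias is low but the model has no external "
            "validation; consider whether a downgrade to high is warranted.")
    return warnings
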