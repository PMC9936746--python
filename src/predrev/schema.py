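"""Domain types for a systematic review of clinical prediction models.

The central object is a :class:`ReviewProject`: an ordered collection of
:class:`ModelRecord` objects (one per prediction model, so a primary study
reporting several models contributes several records), plus the review-wide
configuration — the CHARMS field catalog with its drop-down option lists,
the participant characteristics the review chose to extract, and the
PROBAST signalling-question catalog.

Judgments and answers are closed enumerations.  Severity of a judgment is
totally ordered LOW < UNCLEAR < HIGH; aggregation elsewhere relies on that
order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

SCHEMA_VERSION = 1

#: Maximum number of model records an exported workbook may hold.
WORKBOOK_CAPACITY = 30


class ValidationError(ValueError):
    """Raised when an operation would violate a project invariant."""


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class Judgment(Enum):
    """Risk-of-bias / applicability grade: low, high or unclear."""

    LOW = "LOW"
    HIGH = "HIGH"
    UNCLEAR = "UNCLEAR"

    @property
    def severity(self) -> int:
        return _SEVERITY[self]


_SEVERITY = {Judgment.LOW: 0, Judgment.UNCLEAR: 1, Judgment.HIGH: 2}


class Answer(Enum):
    """Response category for a PROBAST signalling question."""

    YES = "YES"
    PROBABLY_YES = "PROBABLY_YES"
    PROBABLY_NO = "PROBABLY_NO"
    NO = "NO"
    NO_INFORMATION = "NO_INFORMATION"

    @property
    def display(self) -> str:
        return _ANSWER_DISPLAY[self]


_ANSWER_DISPLAY = {
    Answer.YES: "Yes",
    Answer.PROBABLY_YES: "Probably yes",
    Answer.PROBABLY_NO: "Probably no",
    Answer.NO: "No",
    Answer.NO_INFORMATION: "No information",
}


class CharmsDomain(Enum):
    """The eleven CHARMS data-extraction domains, in checklist order."""

    SOURCE_OF_DATA = "SOURCE_OF_DATA"
    PARTICIPANTS = "PARTICIPANTS"
    OUTCOME = "OUTCOME"
    CANDIDATE_PREDICTORS = "CANDIDATE_PREDICTORS"
    SAMPLE_SIZE = "SAMPLE_SIZE"
    MISSING_DATA = "MISSING_DATA"
    MODEL_DEVELOPMENT = "MODEL_DEVELOPMENT"
    MODEL_PERFORMANCE = "MODEL_PERFORMANCE"
    MODEL_EVALUATION = "MODEL_EVALUATION"
    RESULTS = "RESULTS"
    INTERPRETATION = "INTERPRETATION"


class ProbastDomain(Enum):
    """The four PROBAST domains; applicability is assessed for the first three."""

    PARTICIPANTS = "PARTICIPANTS"
    PREDICTORS = "PREDICTORS"
    OUTCOME = "OUTCOME"
    ANALYSIS = "ANALYSIS"

    @property
    def has_applicability(self) -> bool:
        return self is not ProbastDomain.ANALYSIS


APPLICABILITY_DOMAINS = tuple(d for d in ProbastDomain if d.has_applicability)


class FieldState(Enum):
    EMPTY = "EMPTY"
    NO_INFORMATION = "NO_INFORMATION"
    VALUE = "VALUE"


class InputKind(Enum):
    FREE_TEXT = "FREE_TEXT"
    OPTION_LIST = "OPTION_LIST"


# ---------------------------------------------------------------------------
# Value objects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldValue:
    """State of one extraction cell.

    ``EMPTY`` means the reviewer has not filled the cell; ``NO_INFORMATION``
    means the primary study does not report it (and counts as filled for
    completeness purposes); ``VALUE`` carries free text or a drop-down
    option.  Descriptive statistics such as ``"55 (46;66)"`` are stored
    verbatim — the mix of decimal and median(IQR)/mean(SD) conventions in
    real extraction work makes numeric parsing unsafe.
    """

    state: FieldState = FieldState.EMPTY
    text: Optional[str] = None

    def __post_init__(self) -> None:
        if self.state is FieldState.VALUE:
            if self.text is None:
                raise ValidationError("VALUE field requires text")
        elif self.text is not None:
            raise ValidationError(f"{self.state.value} field carries no text")

    @property
    def filled(self) -> bool:
        return self.state is not FieldState.EMPTY

    def render(self, empty: str = "") -> str:
        """Display text: EMPTY -> ``empty``, NO_INFORMATION -> 'No information'."""
        if self.state is FieldState.EMPTY:
            return empty
        if self.state is FieldState.NO_INFORMATION:
            return "No information"
        return self.text  # type: ignore[return-value]


EMPTY = FieldValue()
NO_INFORMATION = FieldValue(FieldState.NO_INFORMATION)


def value(text: str) -> FieldValue:
    """Shorthand for a filled free-text/option cell."""
    return FieldValue(FieldState.VALUE, text)


@dataclass(frozen=True)
class FieldSpec:
    """One CHARMS extraction item: key, label, domain and input kind."""

    key: str
    label: str
    domain: CharmsDomain
    input_kind: InputKind = InputKind.FREE_TEXT
    options: tuple[str, ...] = ()
    required: bool = True

    def __post_init__(self) -> None:
        if self.input_kind is InputKind.OPTION_LIST and len(self.options) < 2:
            raise ValidationError(f"option-list field {self.key!r} needs >= 2 options")
        if self.input_kind is InputKind.FREE_TEXT and self.options:
            raise ValidationError(f"free-text field {self.key!r} cannot carry options")

    def accepts(self, v: FieldValue) -> bool:
        if v.state is not FieldState.VALUE:
            return True
        if self.input_kind is InputKind.OPTION_LIST:
            return v.text in self.options
        return True


@dataclass(frozen=True)
class ParticipantCharacteristicSpec:
    """A review-specific participant characteristic, extracted for every model."""

    key: str
    label: str


@dataclass
class StudyInfo:
    """Bibliographic identity of one model's source study."""

    author: str
    year: int
    identifier: str = ""
    journal: str = ""
    model_name: str = ""
    model_id: str = ""  # assigned by the project; "Author, Year" with letter suffixes


@dataclass
class CharmsRecord:
    values: dict[str, FieldValue] = field(default_factory=dict)
    participant_values: dict[str, FieldValue] = field(default_factory=dict)
    additional_information: str = ""


@dataclass
class ProbastAssessment:
    """Signalling answers plus per-domain and overall judgments.

    ``answers`` maps each domain to a fixed-length list (one slot per
    signalling question; ``None`` = unanswered).  Ratings may be present
    only while every signalling answer of their domain is present — the
    engine enforces that gate.
    """

    answers: dict[ProbastDomain, list[Optional[Answer]]] = field(default_factory=dict)
    rob: dict[ProbastDomain, Optional[Judgment]] = field(default_factory=dict)
    applicability: dict[ProbastDomain, Optional[Judgment]] = field(default_factory=dict)
    overall_rob: Optional[Judgment] = None
    overall_applicability: Optional[Judgment] = None
    overall_rob_override: bool = False
    overall_applicability_override: bool = False


@dataclass
class ModelRecord:
    study: StudyInfo
    charms: CharmsRecord
    probast: ProbastAssessment


# ---------------------------------------------------------------------------
# Default CHARMS field catalog
# ---------------------------------------------------------------------------
# Reconstructed to cover every column the generated tables consume: study
# characteristics (source of data, enrolment, setting, region) and model
# characteristics (method, n/events/missing, candidate predictors, EPV/EPP,
# validation, discrimination, calibration), plus the remaining checklist
# domains (results, interpretation).

_D = CharmsDomain
_OPT = InputKind.OPTION_LIST

DEFAULT_FIELD_CATALOG: tuple[FieldSpec, ...] = (
    FieldSpec("source_of_data", "Source of data", _D.SOURCE_OF_DATA, _OPT,
              ("Existing registry", "Retrospective cohort", "Prospective cohort",
               "Randomized trial", "Other (specify)")),
    FieldSpec("enrolment_period", "Enrolment period", _D.PARTICIPANTS),
    FieldSpec("study_setting", "Study setting", _D.PARTICIPANTS),
    FieldSpec("study_region", "Study region", _D.PARTICIPANTS),
    FieldSpec("inclusion_criteria", "Inclusion criteria", _D.PARTICIPANTS),
    FieldSpec("exclusion_criteria", "Exclusion criteria", _D.PARTICIPANTS),
    FieldSpec("outcome_definition", "Outcome definition", _D.OUTCOME),
    FieldSpec("outcome_timing", "Time point of outcome assessment", _D.OUTCOME),
    FieldSpec("n_candidate_predictors", "Number of candidate predictors", _D.CANDIDATE_PREDICTORS),
    FieldSpec("predictor_measurement", "Timing of predictor measurement", _D.CANDIDATE_PREDICTORS),
    FieldSpec("sample_size", "Sample size (n)", _D.SAMPLE_SIZE),
    FieldSpec("n_events", "Number of events", _D.SAMPLE_SIZE),
    FieldSpec("epv", "Events per variable (EPV)", _D.SAMPLE_SIZE),
    FieldSpec("epp", "Events per parameter (EPP)", _D.SAMPLE_SIZE),
    FieldSpec("n_missing", "Number of participants with missing data", _D.MISSING_DATA),
    FieldSpec("missing_data_handling", "Method for handling missing data", _D.MISSING_DATA, _OPT,
              ("Complete-case analysis", "Multiple imputation", "Single imputation",
               "Not addressed", "Other (specify)")),
    FieldSpec("modelling_method", "Modelling method", _D.MODEL_DEVELOPMENT, _OPT,
              ("Logistic regression", "Cox regression", "Machine learning",
               "Other (specify)")),
    FieldSpec("predictor_selection", "Predictor selection method", _D.MODEL_DEVELOPMENT),
    FieldSpec("discrimination", "Discrimination measures (C-statistic / AUC)", _D.MODEL_PERFORMANCE),
    FieldSpec("calibration", "Calibration measures (HL / CITL / slope)", _D.MODEL_PERFORMANCE),
    FieldSpec("internal_validation", "Internal validation", _D.MODEL_EVALUATION, _OPT,
              ("Bootstrap", "Cross-validation", "Split sample", "None", "Other (specify)")),
    FieldSpec("external_validation", "External validation", _D.MODEL_EVALUATION, _OPT,
              ("Yes", "No", "Other (specify)")),
    FieldSpec("final_model", "Final model (coefficients / score)", _D.RESULTS),
    FieldSpec("model_presentation", "Model presentation", _D.RESULTS),
    FieldSpec("interpretation", "Interpretation of the model", _D.INTERPRETATION),
)


# Default PROBAST signalling-question texts per domain (2 / 3 / 6 / 9).
DEFAULT_SIGNALLING_CATALOG: dict[ProbastDomain, tuple[str, ...]] = {
    ProbastDomain.PARTICIPANTS: (
        "Were appropriate data sources used, e.g. cohort, RCT or nested "
        "case-control study data?",
        "Were all inclusions and exclusions of participants appropriate?",
    ),
    ProbastDomain.PREDICTORS: (
        "Were predictors defined and assessed in a similar way for all participants?",
        "Were predictor assessments made without knowledge of outcome data?",
        "Are all predictors available at the time the model is intended to be used?",
    ),
    ProbastDomain.OUTCOME: (
        "Was the outcome determined appropriately?",
        "Was a prespecified or standard outcome definition used?",
        "Were predictors excluded from the outcome definition?",
        "Was the outcome defined and determined in a similar way for all participants?",
        "Was the outcome determined without knowledge of predictor information?",
        "Was the time interval between predictor assessment and outcome "
        "determination appropriate?",
    ),
    ProbastDomain.ANALYSIS: (
        "Were there a reasonable number of participants with the outcome?",
        "Were continuous and categorical predictors handled appropriately?",
        "Were all enrolled participants included in the analysis?",
        "Were participants with missing data handled appropriately?",
        "Was selection of predictors based on univariable analysis avoided?",
        "Were complexities in the data (e.g. censoring, competing risks) "
        "accounted for appropriately?",
        "Were relevant model performance measures evaluated appropriately?",
        "Were model overfitting and optimism in model performance accounted for?",
        "Do predictors and their assigned weights in the final model correspond "
        "to the results from the reported multivariable analysis?",
    ),
}


# ---------------------------------------------------------------------------
# Project container and record-creation operations
# ---------------------------------------------------------------------------

@dataclass
class ReviewProject:
    title: str
    characteristic_specs: list[ParticipantCharacteristicSpec] = field(default_factory=list)
    field_catalog: list[FieldSpec] = field(default_factory=lambda: list(DEFAULT_FIELD_CATALOG))
    signalling_catalog: dict[ProbastDomain, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SIGNALLING_CATALOG))
    models: list[ModelRecord] = field(default_factory=list)

    def catalog_field(self, key: str) -> FieldSpec:
        for spec in self.field_catalog:
            if spec.key == key:
                return spec
        raise ValidationError(f"unknown field key {key!r}")

    def model(self, model_id: str) -> ModelRecord:
        for rec in self.models:
            if rec.study.model_id == model_id:
                return rec
        raise ValidationError(f"no model with id {model_id!r}")


def new_project(
    title: str,
    characteristic_specs: Iterable[ParticipantCharacteristicSpec] = (),
    field_catalog: Iterable[FieldSpec] | None = None,
) -> ReviewProject:
    """Create a project with the default eleven-domain CHARMS catalog and no models."""
    specs = list(characteristic_specs)
    keys = [s.key for s in specs]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate characteristic key(s): {', '.join(dupes)}")
    catalog = list(field_catalog) if field_catalog is not None else list(DEFAULT_FIELD_CATALOG)
    cat_keys = [s.key for s in catalog]
    if len(set(cat_keys)) != len(cat_keys):
        raise ValidationError("duplicate field key in catalog")
    return ReviewProject(title=title, characteristic_specs=specs, field_catalog=catalog)


_SUFFIX_RE = r" \(([a-z]+)\)"


def _letter_suffix(i: int) -> str:
    # 0 -> 'a', 25 -> 'z', 26 -> 'aa' (spreadsheet-style)
    s = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        s = chr(ord("a") + r) + s
    return s


def _collides(existing_id: str, author: str, year: int) -> bool:
    pat = rf"{re.escape(author)}({_SUFFIX_RE})?, {year}"
    return re.fullmatch(pat, existing_id) is not None


def make_model_id(author: str, year: int, existing_ids: Iterable[str]) -> str:
    """Display identifier "Author, Year", letter-suffixed on author+year collision.

    With no collision the plain form is returned.  When ``existing_ids``
    already contains ids for the same author and year (plain or suffixed),
    the next free suffix in insertion order is used: one existing id yields
    "(b)" for the newcomer (the existing one becomes "(a)" — callers such as
    :func:`add_model` perform that retroactive re-label).
    """
    if not author or not author.strip():
        raise ValidationError("author must be non-empty")
    n_colliding = sum(1 for e in existing_ids if _collides(e, author, year))
    if n_colliding == 0:
        return f"{author}, {year}"
    return f"{author} ({_letter_suffix(n_colliding)}), {year}"


def _blank_record(project: ReviewProject, study: StudyInfo) -> ModelRecord:
    charms = CharmsRecord(
        values={s.key: EMPTY for s in project.field_catalog},
        participant_values={s.key: EMPTY for s in project.characteristic_specs},
    )
    probast = ProbastAssessment(
        answers={d: [None] * len(project.signalling_catalog[d]) for d in ProbastDomain},
        rob={d: None for d in ProbastDomain},
        applicability={d: None for d in APPLICABILITY_DOMAINS},
    )
    return ModelRecord(study=study, charms=charms, probast=probast)


def add_model(project: ReviewProject, study: StudyInfo) -> ModelRecord:
    """Append a fresh record (all CHARMS cells and PROBAST answers empty).

    The model_id is assigned automatically from author and year.  On the
    first collision the previously plain id is retroactively re-labelled
    "(a)" so that suffixes reflect insertion order.  Capacity is not checked
    here — only workbook export enforces the 30-model limit.
    """
    existing = [r.study.model_id for r in project.models]
    new_id = make_model_id(study.author, study.year, existing)
    if new_id != f"{study.author}, {study.year}":
        # retroactively suffix a still-plain colliding id
        plain = f"{study.author}, {study.year}"
        for rec in project.models:
            if rec.study.model_id == plain:
                rec.study.model_id = f"{study.author} ({_letter_suffix(0)}), {study.year}"
    study.model_id = new_id
    record = _blank_record(project, study)
    project.models.append(record)
    return record


def set_field(project: ReviewProject, record: ModelRecord, key: str, v: FieldValue) -> ModelRecord:
    """Store one CHARMS cell; option-list fields reject text outside their options."""
    if key in record.charms.participant_values:
        record.charms.participant_values[key] = v
        return record
    spec = project.catalog_field(key)
    if key not in record.charms.values:
        raise ValidationError(f"record does not carry field {key!r}")
    if not spec.accepts(v):
        raise ValidationError(
            f"{v.text!r} is not an option of field {key!r} "
            f"(allowed: {', '.join(spec.options)})")
    record.charms.values[key] = v
    return record


def set_options(project: ReviewProject, key: str, options: Iterable[str]) -> ReviewProject:
    """Replace the drop-down option list of an option-list field.

    Stored values no longer covered by the new list are NOT erased; they are
    surfaced by :func:`validate_project` as orphaned-option warnings.
    """
    opts = tuple(options)
    spec = project.catalog_field(key)
    if spec.input_kind is not InputKind.OPTION_LIST:
        raise ValidationError(f"field {key!r} is free-text, not an option list")
    if len(opts) < 2:
        raise ValidationError("an option list needs at least 2 options")
    if len(set(opts)) != len(opts):
        raise ValidationError("duplicate options")
    idx = project.field_catalog.index(spec)
    project.field_catalog[idx] = replace(spec, options=opts)
    return project


# ---------------------------------------------------------------------------
# Project-wide validation sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    path: str      # e.g. "models[3].charms.values.source_of_data"
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.severity.upper()} at {self.path}: {self.message}"


def validate_project(project: ReviewProject) -> list[ValidationIssue]:
    """Sweep for invariant violations, reporting each with a field path.

    Errors: duplicate model ids, missing/unknown field keys, ratings stored
    above incomplete signalling answers (gate violations).  Warnings: stored
    option values no longer present in their field's option list.
    """
    issues: list[ValidationIssue] = []
    ids = [r.study.model_id for r in project.models]
    for mid in sorted({i for i in ids if ids.count(i) > 1}):
        issues.append(ValidationIssue("error", "models", f"duplicate model_id {mid!r}"))
    cat = {s.key: s for s in project.field_catalog}
    char_keys = {s.key for s in project.characteristic_specs}
    for i, rec in enumerate(project.models):
        base = f"models[{i}]"
        for key in cat:
            if key not in rec.charms.values:
                issues.append(ValidationIssue(
                    "error", f"{base}.charms.values.{key}", "catalog key missing from record"))
        for key, v in rec.charms.values.items():
            spec = cat.get(key)
            if spec is None:
                issues.append(ValidationIssue(
                    "error", f"{base}.charms.values.{key}", "key not in field catalog"))
            elif not spec.accepts(v):
                issues.append(ValidationIssue(
                    "warning", f"{base}.charms.values.{key}",
                    f"stored value {v.text!r} is not among the field's options"))
        for key in char_keys:
            if key not in rec.charms.participant_values:
                issues.append(ValidationIssue(
                    "error", f"{base}.charms.participant_values.{key}",
                    "characteristic key missing from record"))
        pa = rec.probast
        for d in ProbastDomain:
            expected = len(project.signalling_catalog.get(d, ()))
            got = len(pa.answers.get(d, []))
            if got != expected:
                issues.append(ValidationIssue(
                    "error", f"{base}.probast.answers.{d.value}",
                    f"expected {expected} answer slots, found {got}"))
                continue
            complete = all(a is not None for a in pa.answers[d])
            if not complete:
                if pa.rob.get(d) is not None:
                    issues.append(ValidationIssue(
                        "error", f"{base}.probast.rob.{d.value}",
                        "risk-of-bias rating stored but signalling answers incomplete"))
                if d.has_applicability and pa.applicability.get(d) is not None:
                    issues.append(ValidationIssue(
                        "error", f"{base}.probast.applicability.{d.value}",
                        "applicability rating stored but signalling answers incomplete"))
        if ProbastDomain.ANALYSIS in pa.applicability and \
                pa.applicability[ProbastDomain.ANALYSIS] is not None:
            issues.append(ValidationIssue(
                "error", f"{base}.probast.applicability.ANALYSIS",
                "analysis domain has no applicability assessment"))
    return issues
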