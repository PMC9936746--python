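"""Worked-example and synthetic review projects.

The worked example is an eleven-model review of prognostic models for
mortality after cardiac surgery in infective endocarditis, reconstructed
from its published study-characteristics and risk-of-bias summary tables.
Cells the publication does not print are stored as the explicit
"No information" marker rather than fabricated values, so completeness
flags are exercised honestly.  Three of the models (Gatti (a)/(b)/(c))
come from two primary studies sharing an author and year, exercising the
letter-suffix identifier path; two author names carry diacritics,
exercising encoding round-trips.

``synthetic_review`` generates seeded random projects for property tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from . import probast as _probast
from .schema import (
    APPLICABILITY_DOMAINS,
    Answer,
    FieldState,
    FieldValue,
    InputKind,
    Judgment,
    ModelRecord,
    NO_INFORMATION,
    ParticipantCharacteristicSpec,
    ProbastDomain,
    ReviewProject,
    StudyInfo,
    ValidationError,
    add_model,
    new_project,
    set_field,
    value,
)

_J = {"L": Judgment.LOW, "H": Judgment.HIGH, "U": Judgment.UNCLEAR}

# Per model: author, year, reference tag, then the study-characteristics
# cells (source of data, enrolment period, setting, region, age, native
# valve endocarditis, valve affected; None = "No information") and the
# seven domain judgments (RoB participants/predictors/outcome/analysis,
# applicability participants/predictors/outcome).
_WORKED_EXAMPLE_ROWS: tuple[tuple, ...] = (
    ("Gaca", 2011, "[10]", "Existing registry", "2002—2008",
     "Cardiac surgery centers", "North America",
     "55 (46;66)", None, "All", "HLLH", "LLL"),
    ("De Feo", 2012, "[11]", "Retrospective cohort", "1980—2009",
     "Cardiac surgery center", "Italy",
     "49 (16)", "440 (100)", "All", "HULH", "HLL"),
    ("Martínez-Sellés", 2014, "[12]", "Existing registry", "2008—2010",
     "Cardiac surgery centers", "Spain",
     "61.4 (15.5)", "267 (61.1)", "All", "LLLH", "LLL"),
    ("Madeira", 2016, "[13]", "Retrospective cohort", "2007—2014",
     "Cardiac surgery center", "Portugal",
     "60 (47;70)", "94 (73.4)", "All", "ULLH", "ULL"),
    ("Gatti", 2017, "[14]", "Other (specify)", "2000—2015 (Italy) 2008 (France)",
     "Cardiac surgery centers", "Italy and France",
     "59.1 (15.4)", "285 (78.9)", "All", "LLLH", "LUL"),
    ("Gatti", 2017, "[14]", "Other (specify)", "2000—2015 (Italy) 2008 (France)",
     "Cardiac surgery centers", "Italy and France",
     "59.1 (15.4)", "285 (78.9)", "All", "LLLH", "LLL"),
    ("Di Mauro", 2017, "[15]", "Retrospective cohort", "2000—2015",
     "Cardiac surgery centers", "Italy",
     "59.6 (15.1)", "2.221 (82)", "All", "ULLU", "ULL"),
    ("Gatti", 2017, "[16]", "Retrospective cohort", "1999—2015",
     "Cardiac surgery center", "Italy",
     "60.6 (8.5)", "103 (74.6)", "All", "LLLH", "LLL"),
    ("Olmos", 2017, "[17]", "Retrospective cohort", "1996—2014",
     "Cardiac surgery centers", "Spain",
     "62 (14)", "259 (61.1)", "Aortic / Mitral", "LLLH", "LLL"),
    ("Fernández-Hidalgo", 2018, "[18]", "Retrospective cohort", "2000—2011",
     "Cardiac surgery centers", "Spain",
     "58 (15.1)", None, "All", "LLLL", "LUL"),
    ("Fernández-Hidalgo", 2018, "[18]", "Retrospective cohort", "2000—2011",
     "Cardiac surgery centers", "Spain",
     "58 (15.1)", None, "All", "LLLL", "LLL"),
)

WORKED_EXAMPLE_CHARACTERISTICS = (
    ParticipantCharacteristicSpec("age", "Age of participants"),
    ParticipantCharacteristicSpec("native_valve", "Native valve endocarditis"),
    ParticipantCharacteristicSpec("valve_affected", "Valve affected"),
)


def _fill_remaining_no_information(project: ReviewProject, rec: ModelRecord) -> None:
    for spec in project.field_catalog:
        if rec.charms.values[spec.key].state is FieldState.EMPTY:
            rec.charms.values[spec.key] = NO_INFORMATION
    for cspec in project.characteristic_specs:
        if rec.charms.participant_values[cspec.key].state is FieldState.EMPTY:
            rec.charms.participant_values[cspec.key] = NO_INFORMATION


def worked_example() -> ReviewProject:
    """The eleven-model infective-endocarditis review, fully extracted and rated.

    Study-characteristics cells and all domain judgments carry the
    published values; everything the publication does not print (including
    the signalling answers, which appear only as a figure there) is "No
    information".  Overall judgments are auto-derived, not stored by hand.
    """
    project = new_project(
        "Prognostic models for mortality after cardiac surgery in "
        "infective endocarditis",
        WORKED_EXAMPLE_CHARACTERISTICS,
    )
    for (author, year, ref, source, period, setting, region,
         age, native, valve, rob_str, app_str) in _WORKED_EXAMPLE_ROWS:
        rec = add_model(project, StudyInfo(
            author=author, year=year, identifier=ref, journal="No information"))
        set_field(project, rec, "source_of_data", value(source))
        set_field(project, rec, "enrolment_period", value(period))
        set_field(project, rec, "study_setting", value(setting))
        set_field(project, rec, "study_region", value(region))
        set_field(project, rec, "age", value(age))
        set_field(project, rec, "native_valve",
                  NO_INFORMATION if native is None else value(native))
        set_field(project, rec, "valve_affected", value(valve))
        _fill_remaining_no_information(project, rec)
        for d in ProbastDomain:
            for i in range(len(project.signalling_catalog[d])):
                _probast.answer_signalling(rec, d, i, Answer.NO_INFORMATION)
        for d, code in zip(ProbastDomain, rob_str):
            if d.has_applicability:
                app = _J[app_str[list(APPLICABILITY_DOMAINS).index(d)]]
                _probast.rate(rec, d, _J[code], app)
            else:
                _probast.rate(rec, d, _J[code])
    return project


# ---------------------------------------------------------------------------
# Synthetic reviews
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a randomly generated review project.

    judgment_probs: P(LOW), P(HIGH), P(UNCLEAR) for every domain judgment.
    answer_probs: probabilities of the five signalling-answer categories in
    enum order (yes, probably yes, probably no, no, no information).
    missing_rate: probability that a CHARMS cell is left empty.
    """

    n_models: int = 10
    seed: int = 0
    judgment_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    answer_probs: tuple[float, float, float, float, float] = (
        0.4, 0.2, 0.15, 0.15, 0.1)
    missing_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.n_models < 0:
            raise ValidationError("n_models must be >= 0")
        for name, probs in (("judgment_probs", self.judgment_probs),
                            ("answer_probs", self.answer_probs)):
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must be non-negative and sum to 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValidationError("missing_rate must be in [0, 1]")


_AUTHORS = ("Smith", "García", "Müller", "Chen", "Rossi", "Fernández-Hidalgo",
            "Dubois", "Okafor", "Sørensen", "Martínez-Sellés")
_JUDGMENTS = (Judgment.LOW, Judgment.HIGH, Judgment.UNCLEAR)
_ANSWERS = tuple(Answer)


def synthetic_review(spec: SyntheticSpec) -> ReviewProject:
    """Seeded random project: same spec, same project, bit for bit.

    Every model gets a full set of signalling answers (drawn from
    ``answer_probs``) and domain judgments (drawn independently from
    ``judgment_probs``, entered through the rating gate so overall
    judgments are auto-derived).  Each CHARMS cell is left empty with
    probability ``missing_rate``, otherwise filled — one time in five with
    the "No information" marker, otherwise with an admissible value.
    """
    rng = random.Random(spec.seed)
    project = new_project(
        f"Synthetic review (seed {spec.seed})",
        (ParticipantCharacteristicSpec("age", "Age of participants"),
         ParticipantCharacteristicSpec("sex", "Sex (% female)")),
    )
    for m in range(spec.n_models):
        rec = add_model(project, StudyInfo(
            author=rng.choice(_AUTHORS), year=rng.randint(2000, 2022),
            identifier=f"synthetic:{spec.seed}:{m}", journal="Synthetic Journal"))
        all_keys = ([(s.key, s) for s in project.field_catalog]
                    + [(c.key, None) for c in project.characteristic_specs])
        for key, fspec in all_keys:
            if rng.random() < spec.missing_rate:
                continue
            if rng.random() < 0.2:
                v = NO_INFORMATION
            elif fspec is not None and fspec.input_kind is InputKind.OPTION_LIST:
                v = value(rng.choice(fspec.options))
            else:
                v = value(f"text-{rng.randrange(10_000)}")
            set_field(project, rec, key, v)
        for d in ProbastDomain:
            for i in range(len(project.signalling_catalog[d])):
                ans = rng.choices(_ANSWERS, weights=spec.answer_probs)[0]
                _probast.answer_signalling(rec, d, i, ans)
        for d in ProbastDomain:
            rob = rng.choices(_JUDGMENTS, weights=spec.judgment_probs)[0]
            if d.has_applicability:
                app = rng.choices(_JUDGMENTS, weights=spec.judgment_probs)[0]
                _probast.rate(rec, d, rob, app)
            else:
                _probast.rate(rec, d, rob)
    return project
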