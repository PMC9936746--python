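"""Serialization: project files, table writers, and the eight-sheet workbook.

The canonical store is a structured text project file (YAML or JSON by
extension, versioned schema) — diff-able and versionable.  The workbook is
an interchange view mirroring the spreadsheet template this package models:
eight sheets, with computed values rather than formulas, capped at 30
models.  ``import_workbook`` targets workbooks produced by
``export_workbook``; layouts of third-party spreadsheets are out of scope.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass
from typing import Any, Optional

import yaml

from . import reporting, status
from .reporting import ReportTable
from .schema import (
    APPLICABILITY_DOMAINS,
    SCHEMA_VERSION,
    WORKBOOK_CAPACITY,
    Answer,
    CharmsDomain,
    CharmsRecord,
    FieldSpec,
    FieldState,
    FieldValue,
    InputKind,
    Judgment,
    ModelRecord,
    ParticipantCharacteristicSpec,
    ProbastAssessment,
    ProbastDomain,
    ReviewProject,
    StudyInfo,
    ValidationError,
    validate_project,
)

from importlib.metadata import version as _pkg_version


@dataclass(frozen=True)
class WorkbookLayout:
    """The eight sheets of the template workbook, in order."""

    sheet_names: tuple[str, ...] = (
        "Home", "Summary", "CHARMS", "PROBAST",
        "Study Characteristics", "Model characteristics", "PROBAST summary",
        "CHARMS. Drop-down response lists",
    )
    capacity: int = WORKBOOK_CAPACITY


LAYOUT = WorkbookLayout()


class ProjectValidationError(ValidationError):
    """Carries the full list of validation issues found on load."""

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__("; ".join(str(i) for i in self.issues))


# ---------------------------------------------------------------------------
# Project file (YAML / JSON)
# ---------------------------------------------------------------------------

_JUDGMENT_DISPLAY = {Judgment.LOW: "Low", Judgment.HIGH: "High",
                     Judgment.UNCLEAR: "Unclear"}
_JUDGMENT_FROM_DISPLAY = {v: k for k, v in _JUDGMENT_DISPLAY.items()}
_ANSWER_FROM_DISPLAY = {a.display: a for a in Answer}


def _fv_to_obj(v: FieldValue) -> Any:
    if v.state is FieldState.EMPTY:
        return None
    if v.state is FieldState.NO_INFORMATION:
        return {"no_information": True}
    return v.text


def _fv_from_obj(obj: Any, path: str) -> FieldValue:
    if obj is None:
        return FieldValue()
    if isinstance(obj, dict):
        if obj.get("no_information") is True:
            return FieldValue(FieldState.NO_INFORMATION)
        raise ProjectValidationError(
            [f"error at {path}: unrecognized field value object {obj!r}"])
    if isinstance(obj, str):
        return FieldValue(FieldState.VALUE, obj)
    raise ProjectValidationError([f"error at {path}: bad field value {obj!r}"])


def project_to_dict(project: ReviewProject) -> dict:
    """Plain-data form of a project, with stable key order."""
    return {
        "schema_version": SCHEMA_VERSION,
        "title": project.title,
        "characteristic_specs": [
            {"key": c.key, "label": c.label} for c in project.characteristic_specs],
        "field_catalog": [
            {
                "key": s.key, "label": s.label, "domain": s.domain.value,
                "input_kind": s.input_kind.value,
                "options": list(s.options), "required": s.required,
            }
            for s in project.field_catalog],
        "signalling_catalog": {
            d.value: list(project.signalling_catalog[d]) for d in ProbastDomain},
        "models": [_model_to_dict(m) for m in project.models],
    }


def _model_to_dict(m: ModelRecord) -> dict:
    pa = m.probast
    return {
        "study": {
            "author": m.study.author, "year": m.study.year,
            "identifier": m.study.identifier, "journal": m.study.journal,
            "model_name": m.study.model_name, "model_id": m.study.model_id,
        },
        "charms": {
            "values": {k: _fv_to_obj(v) for k, v in m.charms.values.items()},
            "participant_values": {
                k: _fv_to_obj(v) for k, v in m.charms.participant_values.items()},
            "additional_information": m.charms.additional_information,
        },
        "probast": {
            "answers": {
                d.value: [None if a is None else a.display for a in pa.answers[d]]
                for d in ProbastDomain},
            "rob": {d.value: _opt_j(pa.rob.get(d)) for d in ProbastDomain},
            "applicability": {
                d.value: _opt_j(pa.applicability.get(d))
                for d in APPLICABILITY_DOMAINS},
            "overall_rob": _opt_j(pa.overall_rob),
            "overall_applicability": _opt_j(pa.overall_applicability),
            "overall_rob_override": pa.overall_rob_override,
            "overall_applicability_override": pa.overall_applicability_override,
        },
    }


def _opt_j(j: Optional[Judgment]) -> Optional[str]:
    return None if j is None else _JUDGMENT_DISPLAY[j]


def _j_from(obj: Optional[str], path: str) -> Optional[Judgment]:
    if obj is None:
        return None
    try:
        return _JUDGMENT_FROM_DISPLAY[obj]
    except KeyError:
        raise ProjectValidationError(
            [f"error at {path}: unknown judgment {obj!r}"]) from None


def project_from_dict(data: dict) -> ReviewProject:
    if not isinstance(data, dict):
        raise ProjectValidationError(["error at $: project file is not a mapping"])
    ver = data.get("schema_version")
    if ver != SCHEMA_VERSION:
        raise ProjectValidationError(
            [f"error at schema_version: expected {SCHEMA_VERSION}, found {ver!r}"])
    try:
        catalog = [
            FieldSpec(
                key=f["key"], label=f["label"],
                domain=CharmsDomain(f["domain"]),
                input_kind=InputKind(f["input_kind"]),
                options=tuple(f.get("options", ())),
                required=bool(f.get("required", True)),
            )
            for f in data.get("field_catalog", [])]
    except (KeyError, ValueError, TypeError) as e:
        raise ProjectValidationError([f"error at field_catalog: {e}"]) from None
    chars = [ParticipantCharacteristicSpec(c["key"], c["label"])
             for c in data.get("characteristic_specs", [])]
    sig = {
        d: tuple(data.get("signalling_catalog", {}).get(d.value, ()))
        for d in ProbastDomain}
    project = ReviewProject(
        title=data.get("title", ""), characteristic_specs=chars,
        field_catalog=catalog, signalling_catalog=sig)
    for i, md in enumerate(data.get("models", [])):
        project.models.append(_model_from_dict(md, f"models[{i}]"))
    issues = validate_project(project)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise ProjectValidationError(errors)
    return project


def _model_from_dict(md: dict, path: str) -> ModelRecord:
    s = md.get("study", {})
    try:
        study = StudyInfo(
            author=s["author"], year=int(s["year"]),
            identifier=s.get("identifier", ""), journal=s.get("journal", ""),
            model_name=s.get("model_name", ""), model_id=s.get("model_id", ""))
    except KeyError as e:
        raise ProjectValidationError(
            [f"error at {path}.study: missing {e}"]) from None
    c = md.get("charms", {})
    charms = CharmsRecord(
        values={k: _fv_from_obj(v, f"{path}.charms.values.{k}")
                for k, v in c.get("values", {}).items()},
        participant_values={
            k: _fv_from_obj(v, f"{path}.charms.participant_values.{k}")
            for k, v in c.get("participant_values", {}).items()},
        additional_information=c.get("additional_information", ""))
    p = md.get("probast", {})
    answers: dict[ProbastDomain, list[Optional[Answer]]] = {}
    for d in ProbastDomain:
        raw = p.get("answers", {}).get(d.value, [])
        slots: list[Optional[Answer]] = []
        for j, a in enumerate(raw):
            if a is None:
                slots.append(None)
            elif a in _ANSWER_FROM_DISPLAY:
                slots.append(_ANSWER_FROM_DISPLAY[a])
            else:
                raise ProjectValidationError(
                    [f"error at {path}.probast.answers.{d.value}[{j}]: "
                     f"unknown answer {a!r}"])
        answers[d] = slots
    pa = ProbastAssessment(
        answers=answers,
        rob={d: _j_from(p.get("rob", {}).get(d.value),
                        f"{path}.probast.rob.{d.value}") for d in ProbastDomain},
        applicability={
            d: _j_from(p.get("applicability", {}).get(d.value),
                       f"{path}.probast.applicability.{d.value}")
            for d in APPLICABILITY_DOMAINS},
        overall_rob=_j_from(p.get("overall_rob"), f"{path}.probast.overall_rob"),
        overall_applicability=_j_from(
            p.get("overall_applicability"), f"{path}.probast.overall_applicability"),
        overall_rob_override=bool(p.get("overall_rob_override", False)),
        overall_applicability_override=bool(
            p.get("overall_applicability_override", False)),
    )
    return ModelRecord(study=study, charms=charms, probast=pa)


def save_project(project: ReviewProject, path: str) -> None:
    """Write the project file; format chosen by extension (.yaml/.yml/.json).

    Output is byte-stable: the same project always serializes identically.
    """
    data = project_to_dict(project)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".yaml", ".yml"):
        text = yaml.safe_dump(data, sort_keys=False, allow_unicode=True,
                              default_flow_style=False, width=100)
    elif ext == ".json":
        text = json.dumps(data, indent=2, ensure_ascii=False) + "\n"
    else:
        raise ValidationError(
            f"unknown project file extension {ext!r} (use .yaml, .yml or .json)")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)


def load_project(path: str) -> ReviewProject:
    """Read and validate a project file; violations are reported with field paths."""
    ext = os.path.splitext(path)[1].lower()
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    try:
        if ext in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        elif ext == ".json":
            data = json.loads(text)
        else:
            raise ValidationError(
                f"unknown project file extension {ext!r} (use .yaml, .yml or .json)")
    except (yaml.YAMLError, json.JSONDecodeError) as e:
        raise ValidationError(f"cannot parse {path}: {e}") from None
    return project_from_dict(data)


# ---------------------------------------------------------------------------
# Table writers
# ---------------------------------------------------------------------------

def write_table(table: ReportTable, path: str, dialect: str = "csv") -> None:
    """Write a rendered table as RFC 4180 CSV or a pipe-table Markdown file."""
    if dialect == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(table.header)
            w.writerows(table.rows)
    elif dialect == "markdown":
        def esc(cell: str) -> str:
            return cell.replace("|", "\\|")
        lines = ["| " + " | ".join(esc(h) for h in table.header) + " |",
                 "| " + " | ".join("---" for _ in table.header) + " |"]
        for row in table.rows:
            lines.append("| " + " | ".join(esc(c) for c in row) + " |")
        for note in table.footnotes:
            lines.append("")
            lines.append(note)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unknown table dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Workbook export / import
# ---------------------------------------------------------------------------

_CHARMS_HEADER = ["Model ID", "Section", "Key", "Label", "State", "Value"]
_PROBAST_HEADER = ["Model ID", "Kind", "Domain", "Index", "Text", "Value", "Override"]
_CONFIG_HEADER = ["Section", "Key", "Label", "Domain", "Input kind",
                  "Required", "Options"]
_OPTIONS_SEP = " | "


def export_workbook(project: ReviewProject, path: str) -> None:
    """Write the eight-sheet workbook view of a project.

    Sheets: Home (provenance), Summary (per-model status), CHARMS and
    PROBAST (the raw extraction and assessment data), the three generated
    result tables, and the drop-down/configuration sheet.  Refuses projects
    above the 30-model capacity.
    """
    from openpyxl import Workbook

    if len(project.models) > LAYOUT.capacity:
        raise ValidationError(
            f"workbook capacity is {LAYOUT.capacity} models; "
            f"project has {len(project.models)}")

    wb = Workbook()
    sheets = {}
    import warnings
    for i, name in enumerate(LAYOUT.sheet_names):
        ws = wb.active if i == 0 else wb.create_sheet()
        with warnings.catch_warnings():
            # the drop-down sheet's canonical name exceeds the 31-character
            # convention Excel's UI enforces; openpyxl stores it faithfully
            warnings.simplefilter("ignore", UserWarning)
            ws.title = name
        sheets[name] = ws

    try:
        ver = _pkg_version("predrev")
    except Exception:  # not installed (e.g. direct source checkout)
        ver = "unknown"
    home = sheets["Home"]
    home.append(["CHARMS & PROBAST review project"])
    home.append(["Title", project.title])
    home.append(["Schema version", SCHEMA_VERSION])
    home.append(["Generated by", f"predrev {ver}"])
    home.append(["Capacity", LAYOUT.capacity])
    home.append(["Tools", "CHARMS data-extraction checklist; "
                          "PROBAST risk-of-bias assessment tool"])

    _append_table(sheets["Summary"], status.summary_rows(project))

    ws = sheets["CHARMS"]
    ws.append(_CHARMS_HEADER)
    for rec in project.models:
        mid = rec.study.model_id
        for spec in project.field_catalog:
            v = rec.charms.values[spec.key]
            ws.append([mid, "field", spec.key, spec.label, v.state.value,
                       v.text or ""])
        for cspec in project.characteristic_specs:
            v = rec.charms.participant_values[cspec.key]
            ws.append([mid, "characteristic", cspec.key, cspec.label,
                       v.state.value, v.text or ""])
        ws.append([mid, "additional", "additional_information",
                   "Additional information", "", rec.charms.additional_information])

    ws = sheets["PROBAST"]
    ws.append(_PROBAST_HEADER)
    for rec in project.models:
        mid = rec.study.model_id
        pa = rec.probast
        for d in ProbastDomain:
            for i, ans in enumerate(pa.answers[d]):
                qtext = project.signalling_catalog[d][i]
                ws.append([mid, "answer", d.value, i + 1, qtext,
                           "" if ans is None else ans.display, ""])
            ws.append([mid, "rob", d.value, "", "", _opt_j(pa.rob[d]) or "", ""])
            if d.has_applicability:
                ws.append([mid, "applicability", d.value, "", "",
                           _opt_j(pa.applicability[d]) or "", ""])
        ws.append([mid, "overall_rob", "", "", "", _opt_j(pa.overall_rob) or "",
                   "TRUE" if pa.overall_rob_override else "FALSE"])
        ws.append([mid, "overall_applicability", "", "", "",
                   _opt_j(pa.overall_applicability) or "",
                   "TRUE" if pa.overall_applicability_override else "FALSE"])

    _append_table(sheets["Study Characteristics"],
                  reporting.study_characteristics(project))
    _append_table(sheets["Model characteristics"],
                  reporting.model_characteristics(project))
    _append_table(sheets["PROBAST summary"], reporting.probast_summary(project))

    ws = sheets["CHARMS. Drop-down response lists"]
    ws.append(_CONFIG_HEADER)
    for spec in project.field_catalog:
        ws.append(["field", spec.key, spec.label, spec.domain.value,
                   spec.input_kind.value, "TRUE" if spec.required else "FALSE",
                   _OPTIONS_SEP.join(spec.options)])
    for cspec in project.characteristic_specs:
        ws.append(["characteristic", cspec.key, cspec.label, "", "", "", ""])
    for d in ProbastDomain:
        for i, q in enumerate(project.signalling_catalog[d]):
            ws.append(["signalling", str(i + 1), q, d.value, "", "", ""])

    wb.save(path)


def _append_table(ws, table: ReportTable) -> None:
    ws.append(table.header)
    for row in table.rows:
        ws.append(row)


def _cell(v) -> str:
    return "" if v is None else str(v)


def import_workbook(path: str) -> ReviewProject:
    """Rebuild a project from a workbook written by :func:`export_workbook`.

    The three generated result sheets are computed views and are ignored;
    everything else round-trips.  Unknown judgment/answer strings are
    reported with their cell address.
    """
    from openpyxl import load_workbook
    from predrev import schema as _schema

    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # 31-char title convention
        wb = load_workbook(path, read_only=False, data_only=True)
    for name in LAYOUT.sheet_names:
        if name not in wb.sheetnames:
            raise ValidationError(f"workbook is missing sheet {name!r}")

    title = ""
    for row in wb["Home"].iter_rows(values_only=True):
        if row and _cell(row[0]) == "Title":
            title = _cell(row[1] if len(row) > 1 else "")

    catalog: list[FieldSpec] = []
    chars: list[ParticipantCharacteristicSpec] = []
    sig: dict[ProbastDomain, list[str]] = {d: [] for d in ProbastDomain}
    cfg = wb["CHARMS. Drop-down response lists"]
    for row in list(cfg.iter_rows(values_only=True))[1:]:
        if not row or row[0] is None:
            continue
        section = _cell(row[0])
        if section == "field":
            opts = tuple(o for o in _cell(row[6]).split(_OPTIONS_SEP) if o)
            catalog.append(FieldSpec(
                key=_cell(row[1]), label=_cell(row[2]),
                domain=_schema.CharmsDomain(_cell(row[3])),
                input_kind=InputKind(_cell(row[4])),
                options=opts, required=_cell(row[5]) == "TRUE"))
        elif section == "characteristic":
            chars.append(ParticipantCharacteristicSpec(_cell(row[1]), _cell(row[2])))
        elif section == "signalling":
            sig[ProbastDomain(_cell(row[3]))].append(_cell(row[2]))

    project = ReviewProject(
        title=title, characteristic_specs=chars, field_catalog=catalog,
        signalling_catalog={d: tuple(qs) for d, qs in sig.items()})

    order: list[str] = []
    studies: dict[str, StudyInfo] = {}
    for row in list(wb["Summary"].iter_rows(values_only=True))[1:]:
        if not row or row[0] is None:
            continue
        mid = _cell(row[0])
        order.append(mid)
        studies[mid] = StudyInfo(
            author=_cell(row[1]), year=int(row[2]), identifier=_cell(row[3]),
            journal=_cell(row[4]), model_name=_cell(row[5]), model_id=mid)

    records = {mid: _schema._blank_record(project, studies[mid]) for mid in order}

    ws = wb["CHARMS"]
    for r, row in enumerate(ws.iter_rows(values_only=True), start=1):
        if r == 1 or not row or row[0] is None:
            continue
        mid, section, key = _cell(row[0]), _cell(row[1]), _cell(row[2])
        rec = records[mid]
        if section == "additional":
            rec.charms.additional_information = _cell(row[5])
            continue
        state = FieldState(_cell(row[4]))
        v = (FieldValue(FieldState.VALUE, _cell(row[5]))
             if state is FieldState.VALUE else FieldValue(state))
        if section == "field":
            rec.charms.values[key] = v
        else:
            rec.charms.participant_values[key] = v

    ws = wb["PROBAST"]
    for r, row in enumerate(ws.iter_rows(values_only=True), start=1):
        if r == 1 or not row or row[0] is None:
            continue
        mid, kind = _cell(row[0]), _cell(row[1])
        rec = records[mid]
        raw = _cell(row[5])
        addr = f"{ws.title}!F{r}"
        if kind == "answer":
            d = ProbastDomain(_cell(row[2]))
            idx = int(row[3]) - 1
            if raw == "":
                rec.probast.answers[d][idx] = None
            elif raw in _ANSWER_FROM_DISPLAY:
                rec.probast.answers[d][idx] = _ANSWER_FROM_DISPLAY[raw]
            else:
                raise ValidationError(f"unrecognized answer {raw!r} at {addr}")
        elif kind in ("rob", "applicability"):
            d = ProbastDomain(_cell(row[2]))
            j = _judgment_cell(raw, addr)
            if kind == "rob":
                rec.probast.rob[d] = j
            else:
                rec.probast.applicability[d] = j
        elif kind == "overall_rob":
            rec.probast.overall_rob = _judgment_cell(raw, addr)
            rec.probast.overall_rob_override = _cell(row[6]) == "TRUE"
        elif kind == "overall_applicability":
            rec.probast.overall_applicability = _judgment_cell(raw, addr)
            rec.probast.overall_applicability_override = _cell(row[6]) == "TRUE"

    project.models = [records[mid] for mid in order]
    issues = validate_project(project)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise ProjectValidationError(errors)
    return project


def _judgment_cell(raw: str, addr: str) -> Optional[Judgment]:
    if raw == "":
        return None
    if raw in _JUDGMENT_FROM_DISPLAY:
        return _JUDGMENT_FROM_DISPLAY[raw]
    raise ValidationError(f"unrecognized judgment {raw!r} at {addr}")
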