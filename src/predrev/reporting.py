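"""Publication-ready outputs: summary tables and the judgment-distribution figure.

Tables are produced as a neutral :class:`ReportTable` (header + string
cells); CSV/Markdown/XLSX serialization lives in :mod:`predrev.io` so this
module stays format-free.  Judgments are rendered with the conventional
traffic-light symbols: ``+`` low, ``-`` high, ``?`` unclear.  Cells that
have not been rated at all render blank, never ``?`` — "unclear" is a
judgment, "not done" is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import probast as _probast
from .schema import (
    APPLICABILITY_DOMAINS,
    Judgment,
    ModelRecord,
    ProbastDomain,
    ReviewProject,
    ValidationError,
)

_SYMBOL = {Judgment.LOW: "+", Judgment.HIGH: "-", Judgment.UNCLEAR: "?"}
_FROM_SYMBOL = {v: k for k, v in _SYMBOL.items()}

_DOMAIN_TITLE = {
    ProbastDomain.PARTICIPANTS: "Participants",
    ProbastDomain.PREDICTORS: "Predictors",
    ProbastDomain.OUTCOME: "Outcome",
    ProbastDomain.ANALYSIS: "Analysis",
}

#: The nine assessment columns of the summary table / distribution figure.
ASSESSMENT_COLUMNS: tuple[str, ...] = tuple(
    [f"RoB {i}. {_DOMAIN_TITLE[d]}" for i, d in enumerate(ProbastDomain, 1)]
    + [f"Applicability {i}. {_DOMAIN_TITLE[d]}"
       for i, d in enumerate(APPLICABILITY_DOMAINS, 1)]
    + ["Overall RoB", "Overall Applicability"]
)


def symbol(j: Judgment) -> str:
    """Traffic-light symbol: low ``+``, high ``-``, unclear ``?``."""
    return _SYMBOL[j]


def judgment_from_symbol(s: str) -> Judgment:
    try:
        return _FROM_SYMBOL[s]
    except KeyError:
        raise ValidationError(f"unrecognized judgment symbol {s!r}") from None


@dataclass
class ReportTable:
    """A rendered table: title, column labels, string cells, footnotes."""

    title: str
    header: list[str]
    rows: list[list[str]] = field(default_factory=list)
    footnotes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, row in enumerate(self.rows):
            if len(row) != len(self.header):
                raise ValidationError(
                    f"row {i} has {len(row)} cells, header has {len(self.header)}")


def _opt_symbol(j: Optional[Judgment]) -> str:
    return "" if j is None else _SYMBOL[j]


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def study_characteristics(project: ReviewProject) -> ReportTable:
    """Study-characteristics table: source of data, enrolment period, study
    setting and region, then the review's pre-defined participant
    characteristics — one row per model in project order."""
    header = ["Author, Year", "Source of data", "Enrolment period",
              "Study setting", "Study region"]
    header += [c.label for c in project.characteristic_specs]
    rows = []
    for rec in project.models:
        row = [rec.study.model_id]
        for key in ("source_of_data", "enrolment_period", "study_setting",
                    "study_region"):
            row.append(rec.charms.values[key].render())
        for c in project.characteristic_specs:
            row.append(rec.charms.participant_values[c.key].render())
        rows.append(row)
    return ReportTable(title="Study Characteristics", header=header, rows=rows)


_MODEL_CHAR_FOOTNOTE = (
    "+ Low RoB or low concern for applicability; - High RoB or high concern "
    "for applicability; ? Unclear RoB or applicability")


def model_characteristics(project: ReviewProject) -> ReportTable:
    """Model-characteristics table: modelling choices, sample size and
    performance summary per model, plus the seven per-domain judgment
    symbols.  Always 10 descriptive + 7 symbol columns."""
    header = [
        "Author, Year", "Modelling method", "n / events / missing",
        "Candidate predictors", "EPV", "EPP", "Internal validation",
        "External validation", "Discrimination", "Calibration",
        "RoB Participants", "RoB Predictors", "RoB Outcome", "RoB Analysis",
        "App Participants", "App Predictors", "App Outcome",
    ]
    rows = []
    for rec in project.models:
        v = rec.charms.values
        nem = " / ".join(v[k].render() for k in ("sample_size", "n_events", "n_missing"))
        row = [
            rec.study.model_id,
            v["modelling_method"].render(),
            nem,
            v["n_candidate_predictors"].render(),
            v["epv"].render(),
            v["epp"].render(),
            v["internal_validation"].render(),
            v["external_validation"].render(),
            v["discrimination"].render(),
            v["calibration"].render(),
        ]
        row += [_opt_symbol(rec.probast.rob.get(d)) for d in ProbastDomain]
        row += [_opt_symbol(rec.probast.applicability.get(d))
                for d in APPLICABILITY_DOMAINS]
        rows.append(row)
    return ReportTable(title="Model characteristics", header=header, rows=rows,
                       footnotes=[_MODEL_CHAR_FOOTNOTE])


def probast_summary(project: ReviewProject) -> ReportTable:
    """Risk-of-bias / applicability symbol table, one row per model.

    The seven domain columns come from the stored ratings; the two overall
    columns are computed by the worst-rating aggregation (honouring manual
    overrides), never read back from stored cells.
    """
    header = ["Author, Year",
              "RoB 1. Participants", "RoB 2. Predictors", "RoB 3. Outcome",
              "RoB 4. Analysis",
              "Applicability 1. Participants", "Applicability 2. Predictors",
              "Applicability 3. Outcome",
              "Overall Risk of Bias", "Overall Applicability"]
    rows = []
    for rec in project.models:
        row = [rec.study.model_id]
        row += [_opt_symbol(rec.probast.rob.get(d)) for d in ProbastDomain]
        row += [_opt_symbol(rec.probast.applicability.get(d))
                for d in APPLICABILITY_DOMAINS]
        try:
            ov_rob, ov_app = _probast.overall(rec)
            row += [symbol(ov_rob), symbol(ov_app)]
        except ValidationError:
            row += ["", ""]
        rows.append(row)
    return ReportTable(title="PROBAST summary", header=header, rows=rows,
                       footnotes=[_MODEL_CHAR_FOOTNOTE])


# ---------------------------------------------------------------------------
# Judgment distribution and figure
# ---------------------------------------------------------------------------

@dataclass
class DistributionSummary:
    """Percentage of rated models judged low/high/unclear, per assessment
    column (four RoB domains + overall RoB; three applicability domains +
    overall applicability)."""

    columns: list[str]
    percentages: dict[str, dict[Judgment, float]]
    n_models: int

    def __post_init__(self) -> None:
        for col in self.columns:
            total = sum(self.percentages[col].values())
            if abs(total - 100.0) > 0.01:
                raise ValidationError(f"column {col!r} percentages sum to {total}")


def _rated_judgments(rec: ModelRecord) -> Optional[dict[str, Judgment]]:
    """All nine judgments of a fully assessed model, or None if any missing."""
    pa = rec.probast
    if any(pa.rob.get(d) is None for d in ProbastDomain):
        return None
    if any(pa.applicability.get(d) is None for d in APPLICABILITY_DOMAINS):
        return None
    ov_rob, ov_app = _probast.overall(rec)
    out: dict[str, Judgment] = {}
    for i, d in enumerate(ProbastDomain, 1):
        out[f"RoB {i}. {_DOMAIN_TITLE[d]}"] = pa.rob[d]
    for i, d in enumerate(APPLICABILITY_DOMAINS, 1):
        out[f"Applicability {i}. {_DOMAIN_TITLE[d]}"] = pa.applicability[d]
    out["Overall RoB"] = ov_rob
    out["Overall Applicability"] = ov_app
    return out


def distribution(project: ReviewProject) -> DistributionSummary:
    """Judgment distribution over models with a complete assessment."""
    rated = [j for rec in project.models if (j := _rated_judgments(rec)) is not None]
    if not rated:
        raise ValidationError("no model has a complete assessment")
    n = len(rated)
    pct: dict[str, dict[Judgment, float]] = {}
    for col in ASSESSMENT_COLUMNS:
        counts = {j: 0 for j in Judgment}
        for judged in rated:
            counts[judged[col]] += 1
        pct[col] = {j: 100.0 * c / n for j, c in counts.items()}
    return DistributionSummary(columns=list(ASSESSMENT_COLUMNS),
                               percentages=pct, n_models=n)


_FIGURE_COLORS = {
    Judgment.LOW: "#2e7d32",      # green
    Judgment.HIGH: "#c62828",     # red
    Judgment.UNCLEAR: "#f9a825",  # amber
}
_FIGURE_LABELS = {Judgment.LOW: "Low", Judgment.HIGH: "High",
                  Judgment.UNCLEAR: "Unclear"}


def render_figure(
    d: DistributionSummary,
    path: str,
    include_overall: bool = True,
) -> list[str]:
    """Horizontal stacked-bar chart of the judgment distribution.

    One bar per assessment column (top = first), green/red/amber segments
    for low/high/unclear.  Written as both PNG and SVG next to ``path``
    (extension replaced); returns the written paths.  SVG output is
    byte-deterministic for a given distribution.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = [c for c in d.columns if include_overall or not c.startswith("Overall")]
    fig, ax = plt.subplots(figsize=(8, 0.45 * len(cols) + 1.2))
    y = list(range(len(cols)))[::-1]  # first column on top
    left = [0.0] * len(cols)
    for j in (Judgment.LOW, Judgment.HIGH, Judgment.UNCLEAR):
        widths = [d.percentages[c][j] for c in cols]
        bars = ax.barh(y, widths, left=left, color=_FIGURE_COLORS[j],
                       edgecolor="white", label=_FIGURE_LABELS[j])
        for bar, c in zip(bars, cols):
            bar.set_gid(f"seg::{c}::{j.value}")
        left = [l + w for l, w in zip(left, widths)]
    ax.set_yticks(y)
    ax.set_yticklabels(cols, fontsize=8)
    ax.set_xlim(0, 100)
    ax.set_xlabel("Percentage of models (%)")
    ax.legend(loc="lower right", fontsize=8, framealpha=1.0)
    ax.set_title(f"Risk of bias and applicability (n = {d.n_models} models)")
    fig.tight_layout()

    import os
    stem, _ = os.path.splitext(path)
    written = []
    with matplotlib.rc_context({"svg.hashsalt": "predrev"}):
        for ext in (".png", ".svg"):
            out = stem + ext
            fig.savefig(out, metadata=_figure_metadata(ext), dpi=150)
            written.append(out)
    plt.close(fig)
    return written


def _figure_metadata(ext: str) -> dict:
    # strip run-dependent timestamps so repeated renders are byte-identical
    if ext == ".svg":
        return {"Date": None}
    return {"Software": None}
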