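# Methods

## The workflow being modelled

`predrev` encodes the standard two-instrument workflow for systematic
reviews of clinical prediction models as typed, validated software. A
review is a `ReviewProject`: review-wide configuration (the CHARMS field
catalog with drop-down option lists, the participant characteristics to
extract, the PROBAST signalling-question catalog) plus one `ModelRecord`
per prediction model. The unit of analysis is the *model*, not the study:
a primary study reporting two models contributes two records that share
bibliographic metadata.

### Identifiers

Display identifiers are `"Author, Year"`. When two records collide on
author and year, all colliding records receive letter suffixes in
insertion order (`Gatti (a), 2017`, `Gatti (b), 2017`, …); the first
record is re-labelled retroactively at the moment the second is added, so
a plain and a suffixed form never coexist. Replaying the same insertion
order reproduces identical identifiers, and identifiers are pairwise
distinct after any insertion sequence (both property-tested). Suffixes
continue `z → aa` in spreadsheet style, though reviews that deep are not
realistic (workbook capacity is 30).

### Extraction cells and completeness

Every CHARMS cell is in one of three states: `EMPTY` (not yet processed),
`NO_INFORMATION` (the study does not report it), or `VALUE` (free text or
a drop-down option). The distinction matters because completeness is a
workflow property, not a data property: a domain is complete when every
required cell is filled, and "No information" is a legitimate fill.
Statistics such as `55 (46;66)` or `2.221 (82)` are stored verbatim —
published tables mix decimal conventions and median(IQR)/mean(SD) formats,
so numeric parsing would corrupt data silently.

All catalog fields default to `required=True`; per-field relaxation is
available for review-specific tailoring. The free-text "additional
information" line is optional and never affects completeness. Replacing an
option list never erases stored values; values orphaned by the new list
are surfaced as warnings by the project-wide validation sweep.

The exact item granularity of the original extraction sheet is not fully
standardised across reviews, so the default catalog is a reconstruction
that covers every column the generated tables consume (source of data,
enrolment period, setting, region, outcome, candidate predictors, sample
size / events / missing, EPV, EPP, modelling method, predictor selection,
internal/external validation, discrimination, calibration, presentation,
interpretation) and is fully configurable.

### Assessment gating and aggregation

Signalling answers live in fixed-length slots per domain (2 / 3 / 6 / 9 in
the default catalog, which ships the published question texts as
configuration). Ratings are gated: a domain's risk-of-bias and
applicability judgments can be stored only while all of its signalling
answers are present. Clearing an answer *clears* (not merely hides) the
dependent ratings — the invariant "ratings exist only above complete
answers" survives any operation sequence, is enforced again at load time,
and is property-tested under random operation streams. The spreadsheet
the workflow descends from leaves its behaviour here unspecified; clearing
is the safe choice because a hidden-but-stale rating could silently
resurface.

Overall judgments use the worst-rating rule: high if any domain is high,
else unclear if any is unclear, else low — equivalently the maximum under
the severity order low < unclear < high (verified exhaustively against a
brute-force maximum over all 3⁴ + 3³ = 108 combinations). They are
auto-derived whenever the ratings are complete. Because the source
workflow has reviewers *rate* the overall cells, a manual override is
provided: an overridden value is stored, flagged, survives re-rating, and
is released explicitly. Every overall cell in the worked example is
consistent with the automatic rule, so the fixture stores no overrides.

`suggest_rating` maps a domain's answers to an advisory judgment (any
negative answer → high, else any "no information" → unclear, else low).
It is advisory only and never auto-applied: signalling questions inform
but do not mechanically determine the judgment. Similarly, the published
guidance that a development-only model rated low overall may be downgraded
to high is surfaced as a warning (`validation_warnings`) when external
validation is recorded as "No", never applied automatically.

### Reporting

Tables are built as a neutral `ReportTable` (title, header, string rows,
footnotes; rectangularity enforced at construction) and serialized
elsewhere, so the table logic is format-free. Judgment symbols follow the
evidence-synthesis convention `+` / `-` / `?`; cells that were never rated
render blank rather than `?`, to avoid conflating "unclear" (a judgment)
with "not done". The summary table's two overall columns are computed by
the aggregation rule at render time, never read from stored cells.

The distribution figure draws one horizontal stacked bar per assessment
column (four RoB domains + overall RoB, three applicability domains +
overall applicability; the overall bars can be excluded via
`include_overall=False`, since conventions differ), green/red/amber for
low/high/unclear. SVG output is byte-deterministic (fixed hash salt, no
timestamp metadata) so renders can be diffed; each segment carries a
machine-readable `gid`, which the tests use to verify that drawn widths
are proportional to percentages.

### Serialization

The canonical store is a versioned YAML/JSON project file with stable key
order (byte-stable serialization). The eight-sheet workbook is an
interchange view: Home (provenance), Summary (status flags), CHARMS and
PROBAST (raw data in a tabular layout), the three generated result sheets
(computed values, no formulas), and the drop-down/configuration sheet.
Export enforces the 30-model capacity; import targets only workbooks
produced by export (third-party spreadsheet layouts are out of scope) and
reports unknown judgment or answer strings with their cell address. Load
runs the validation sweep and rejects files with structural or gating
errors, listing each with its field path. The canonical drop-down sheet
name is 32 characters, one beyond the limit Excel's UI enforces; openpyxl
stores and reads it faithfully, so the canonical name is kept.

## The worked example

The packaged fixture reconstructs an eleven-model review of prognostic
models for mortality after cardiac surgery in infective endocarditis from
its two published summary tables: all study-characteristics cells
(including the "No information" cells and the diacritic-bearing author
names) and all seven domain judgments per model. Everything the
publication does not print — the remaining CHARMS cells and all signalling
answers — is stored as "No information" rather than invented, so
completeness flags are exercised honestly and the rating gate is open for
a documented reason. Three Gatti 2017 models (two sharing one primary
study) exercise the multi-model-per-study and suffixing paths. Study
identifiers use the review's bracketed reference tags (`[10]`…`[18]`).
Overall judgments in the fixture are auto-derived, and the tests confirm
they reproduce the published overall columns cell for cell.

## The synthetic generator

`synthetic_review(SyntheticSpec)` produces seeded, reproducible projects
for property tests: authors drawn from a diacritic-bearing pool (so
collisions and encoding are exercised), every signalling question answered
from a five-category probability vector, every domain judgment drawn from
a low/high/unclear probability vector and entered through the rating gate,
and each CHARMS cell left empty with probability `missing_rate` (filled
cells are "No information" one time in five, otherwise an admissible
value). Defaults — 10 models, judgment probabilities (0.5, 0.3, 0.2),
answer probabilities (0.4, 0.2, 0.15, 0.15, 0.1), 10 % missing — are
chosen to resemble the mix observed in published prediction-model reviews,
where high-risk judgments are common and extraction gaps are routine.

What the generator does *not* emulate: correlations between answers and
judgments (judgments are drawn independently of the answers, since the
instrument itself leaves that mapping to reviewer judgment), realistic
performance statistics (cells hold synthetic text), and multi-reviewer
disagreement. Passing property tests therefore demonstrate invariant
preservation under arbitrary well-formed data, not fidelity of any
particular clinical review.

## Problem sizes and numerical choices

The test suite checks invariants over ≥ 1,000 generated models (100
projects of 10) plus exhaustive enumeration of all 108 judgment
combinations; the acceptance script uses five 8-model projects for its
seeded round-trip check. These sizes fully exercise every code path while
keeping the suite fast. There is no floating-point computation beyond
percentages; the only tolerance in the package is the 0.01 slack on the
per-column 100 % sum in `DistributionSummary`, which absorbs rounding.

## Known limitations

- Single-record model: no multi-reviewer extraction or conflict
  resolution, no per-reviewer progress or timestamps.
- Import is an inverse of export only; filled copies of the original
  spreadsheet template with user-modified layouts are not parsed.
- The prognostic-model wording of the signalling questions is shipped;
  diagnostic-model variants and the short-form instrument are not.
- Generated workbooks contain values, not formulas: opening one in a
  spreadsheet gives a snapshot, not a live template.
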