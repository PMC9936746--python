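# predrev

Structured data extraction and risk-of-bias assessment for **systematic
reviews of clinical prediction models**.

Reviews of prognostic and diagnostic models rely on two standard
instruments: the **CHARMS** checklist (CHecklist for critical Appraisal and
data extraction for systematic Reviews of prediction Modelling Studies),
which organises data extraction into eleven domains — source of data,
participants, outcome, candidate predictors, sample size, missing data,
model development, model performance, model evaluation, results,
interpretation — and the **PROBAST** tool (Prediction model Risk Of Bias
ASsessment Tool), which grades risk of bias in four domains (participants,
predictors, outcome, analysis) and applicability concerns in the first
three, each as *low*, *high* or *unclear*, informed by signalling questions
answered *yes / probably yes / probably no / no / no information*.

`predrev` implements this combined workflow as a library and CLI:

- **Extraction records** per model (a study reporting several models gets
  several records) with configurable drop-down option lists, explicit
  "No information" markers, and automatic `Author, Year` identifiers that
  gain letter suffixes — `Gatti (a), 2017`, `Gatti (b), 2017` — on
  author/year collisions.
- **Completeness tracking**: a CHARMS domain is complete when every
  required cell is filled ("No information" counts, an empty cell does
  not); a model is flagged *"All information has been successfully
  registered"* or *"Incomplete data extraction"*.
- **Assessment gating**: a domain's risk-of-bias and applicability ratings
  become editable only once all of its signalling questions are answered
  (2 / 3 / 6 / 9 questions for participants / predictors / outcome /
  analysis), and are cleared if an answer is later removed.
- **Overall judgments** via the worst-rating rule

  $$\mathrm{overall} = \max_{d}\; j_d, \qquad \text{low} < \text{unclear} < \text{high},$$

  i.e. *high* if any domain is high, else *unclear* if any is unclear,
  else *low* — auto-derived with an explicit manual-override mechanism.
- **Publication-ready outputs**: study-characteristics and
  model-characteristics tables, the traffic-light summary table
  (`+` low, `-` high, `?` unclear), a stacked-bar judgment-distribution
  figure (PNG + deterministic SVG), CSV/Markdown writers, and an
  eight-sheet XLSX workbook (capacity 30 models) that round-trips.

## Worked example

The package ships an eleven-model review of prognostic models for
mortality after cardiac surgery in infective endocarditis as a regenerable
fixture:

```sh
predrev fixtures --out review.yaml
predrev status --project review.yaml
```

```text
Model ID                     Author             Year  ...  CHARMS status                                     PROBAST status
---------------------------  -----------------  ----  ...  ------------------------------------------------  --------------
Gaca, 2011                   Gaca               2011  ...  All information has been successfully registered  Complete
De Feo, 2012                 De Feo             2012  ...  All information has been successfully registered  Complete
Martínez-Sellés, 2014        Martínez-Sellés    2014  ...  All information has been successfully registered  Complete
...
```

All eleven models are fully extracted and assessed. Rendering the reports:

```sh
predrev report --project review.yaml --out out/
head -3 out/probast_summary.csv
```

```text
"Author, Year",RoB 1. Participants,RoB 2. Predictors,RoB 3. Outcome,RoB 4. Analysis,Applicability 1. Participants,Applicability 2. Predictors,Applicability 3. Outcome,Overall Risk of Bias,Overall Applicability
"Gaca, 2011",-,+,+,-,+,+,+,-,+
"De Feo, 2012",-,?,+,-,-,+,+,-,-
```

Reading the Gaca row: high risk of bias in the participants and analysis
domains (`-`), low in predictors and outcome (`+`), low applicability
concern everywhere — so the overall risk of bias aggregates to high and
overall applicability to low. Across the review the overall risk-of-bias
column splits 18.2 % low, 72.7 % high, 9.1 % unclear (2 / 8 / 1 of 11
models); the figure in `out/probast_summary_figure.png` draws one stacked
bar per assessment column with these proportions.

The same project exports to the eight-sheet workbook and back:

```sh
predrev export --project review.yaml --out review.xlsx
predrev import --workbook review.xlsx --project back.yaml   # identical project
```

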