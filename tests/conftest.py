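import pytest

from predrev import worked_example


@pytest.fixture()
def worked():
    """Fresh worked-example project (11 endocarditis models)."""
    return worked_example()


# The published study-characteristics table, decoded cell by cell.
# Columns: Author-Year id, Source of data, Enrolment period, Study setting,
# Study region, Age of participants, Native valve endocarditis, Valve affected.
TABLE_STUDY_CHARACTERISTICS = [
    ["Gaca, 2011", "Existing registry", "2002—2008", "Cardiac surgery centers",
     "North America", "55 (46;66)", "No information", "All"],
    ["De Feo, 2012", "Retrospective cohort", "1980—2009", "Cardiac surgery center",
     "Italy", "49 (16)", "440 (100)", "All"],
    ["Martínez-Sellés, 2014", "Existing registry", "2008—2010",
     "Cardiac surgery centers", "Spain", "61.4 (15.5)", "267 (61.1)", "All"],
    ["Madeira, 2016", "Retrospective cohort", "2007—2014", "Cardiac surgery center",
     "Portugal", "60 (47;70)", "94 (73.4)", "All"],
    ["Gatti (a), 2017", "Other (specify)", "2000—2015 (Italy) 2008 (France)",
     "Cardiac surgery centers", "Italy and France", "59.1 (15.4)", "285 (78.9)", "All"],
    ["Gatti (b), 2017", "Other (specify)", "2000—2015 (Italy) 2008 (France)",
     "Cardiac surgery centers", "Italy and France", "59.1 (15.4)", "285 (78.9)", "All"],
    ["Di Mauro, 2017", "Retrospective cohort", "2000—2015",
     "Cardiac surgery centers", "Italy", "59.6 (15.1)", "2.221 (82)", "All"],
    ["Gatti (c), 2017", "Retrospective cohort", "1999—2015",
     "Cardiac surgery center", "Italy", "60.6 (8.5)", "103 (74.6)", "All"],
    ["Olmos, 2017", "Retrospective cohort", "1996—2014", "Cardiac surgery centers",
     "Spain", "62 (14)", "259 (61.1)", "Aortic / Mitral"],
    ["Fernández-Hidalgo (a), 2018", "Retrospective cohort", "2000—2011",
     "Cardiac surgery centers", "Spain", "58 (15.1)", "No information", "All"],
    ["Fernández-Hidalgo (b), 2018", "Retrospective cohort", "2000—2011",
     "Cardiac surgery centers", "Spain", "58 (15.1)", "No information", "All"],
]

# The published risk-of-bias summary, one row per model: RoB for
# participants/predictors/outcome/analysis, applicability for
# participants/predictors/outcome, then the two overall columns.
TABLE_PROBAST_SUMMARY = [
    ["Gaca, 2011", "-", "+", "+", "-", "+", "+", "+", "-", "+"],
    ["De Feo, 2012", "-", "?", "+", "-", "-", "+", "+", "-", "-"],
    ["Martínez-Sellés, 2014", "+", "+", "+", "-", "+", "+", "+", "-", "+"],
    ["Madeira, 2016", "?", "+", "+", "-", "?", "+", "+", "-", "?"],
    ["Gatti (a), 2017", "+", "+", "+", "-", "+", "?", "+", "-", "?"],
    ["Gatti (b), 2017", "+", "+", "+", "-", "+", "+", "+", "-", "+"],
    ["Di Mauro, 2017", "?", "+", "+", "?", "?", "+", "+", "?", "?"],
    ["Gatti (c), 2017", "+", "+", "+", "-", "+", "+", "+", "-", "+"],
    ["Olmos, 2017", "+", "+", "+", "-", "+", "+", "+", "-", "+"],
    ["Fernández-Hidalgo (a), 2018", "+", "+", "+", "+", "+", "?", "+", "+", "?"],
    ["Fernández-Hidalgo (b), 2018", "+", "+", "+", "+", "+", "+", "+", "+", "+"],
]
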