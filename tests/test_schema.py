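"""Record creation, automatic model identifiers, field and option handling."""

import pytest
from hypothesis import given, settings, strategies as st

from predrev import (
    CharmsDomain,
    FieldSpec,
    FieldState,
    FieldValue,
    InputKind,
    NO_INFORMATION,
    ParticipantCharacteristicSpec,
    StudyInfo,
    ValidationError,
    add_model,
    make_model_id,
    new_project,
    set_field,
    set_options,
    validate_project,
    value,
)
from predrev.schema import DEFAULT_FIELD_CATALOG


def _proj(chars=()):
    return new_project("Test review", chars)


class TestNewProject:
    def test_characteristic_columns(self):
        p = _proj([ParticipantCharacteristicSpec("age", "Age of participants"),
                   ParticipantCharacteristicSpec("nve", "Native valve endocarditis"),
                   ParticipantCharacteristicSpec("valve", "Valve affected")])
        assert [c.label for c in p.characteristic_specs] == [
            "Age of participants", "Native valve endocarditis", "Valve affected"]
        assert p.models == []

    def test_default_catalog_spans_all_eleven_domains(self):
        p = _proj()
        assert {s.domain for s in p.field_catalog} == set(CharmsDomain)
        assert len(CharmsDomain) == 11

    def test_zero_characteristics_allowed(self):
        assert _proj([]).characteristic_specs == []

    def test_duplicate_characteristic_key_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            _proj([ParticipantCharacteristicSpec("a", "A"),
                   ParticipantCharacteristicSpec("a", "A again")])


class TestMakeModelId:
    def test_plain_author_year(self):
        assert make_model_id("Madeira", 2016, []) == "Madeira, 2016"

    def test_next_suffix_after_existing_lettered_id(self):
        got = make_model_id("Fernández-Hidalgo", 2018,
                            ["Fernández-Hidalgo (a), 2018"])
        assert got == "Fernández-Hidalgo (b), 2018"

    def test_empty_author_rejected(self):
        with pytest.raises(ValidationError):
            make_model_id("", 2000, [])

    def test_same_author_different_year_does_not_collide(self):
        assert make_model_id("Gatti", 2018, ["Gatti, 2017"]) == "Gatti, 2018"


class TestAddModel:
    def test_fresh_record_is_empty(self):
        p = _proj([ParticipantCharacteristicSpec("age", "Age")])
        rec = add_model(p, StudyInfo(author="De Feo", year=2012))
        assert rec.study.model_id == "De Feo, 2012"
        assert all(v.state is FieldState.EMPTY for v in rec.charms.values.values())
        assert all(v.state is FieldState.EMPTY
                   for v in rec.charms.participant_values.values())
        assert all(a is None for slots in rec.probast.answers.values()
                   for a in slots)

    def test_collision_relabels_first_id_retroactively(self):
        p = _proj()
        first = add_model(p, StudyInfo(author="A", year=2000))
        assert first.study.model_id == "A, 2000"
        second = add_model(p, StudyInfo(author="A", year=2000))
        assert first.study.model_id == "A (a), 2000"
        assert second.study.model_id == "A (b), 2000"

    def test_three_way_collision_across_studies(self):
        # two models from one study plus one from another, same author+year
        p = _proj()
        for ident in ("[14]", "[14]", "[16]"):
            add_model(p, StudyInfo(author="Gatti", year=2017, identifier=ident))
        assert [m.study.model_id for m in p.models] == [
            "Gatti (a), 2017", "Gatti (b), 2017", "Gatti (c), 2017"]

    def test_capacity_not_enforced_in_memory(self):
        p = _proj()
        for i in range(31):
            add_model(p, StudyInfo(author=f"Author{i}", year=2000 + i))
        assert len(p.models) == 31  # only workbook export enforces the limit

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from(["Ae", "Bo", "Cy", "Dü"]),
                              st.integers(2000, 2003)), max_size=25))
    def test_ids_always_pairwise_distinct(self, stream):
        p = _proj()
        for author, year in stream:
            add_model(p, StudyInfo(author=author, year=year))
        ids = [m.study.model_id for m in p.models]
        assert len(set(ids)) == len(ids)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from(["Ae", "Bo"]),
                              st.integers(2000, 2002)), max_size=15))
    def test_suffixing_is_stable_under_replay(self, stream):
        p1, p2 = _proj(), _proj()
        for author, year in stream:
            add_model(p1, StudyInfo(author=author, year=year))
        for author, year in stream:
            add_model(p2, StudyInfo(author=author, year=year))
        assert [m.study.model_id for m in p1.models] == \
               [m.study.model_id for m in p2.models]


class TestSetField:
    def test_option_value_accepted(self):
        p = _proj()
        rec = add_model(p, StudyInfo(author="X", year=2000))
        set_field(p, rec, "source_of_data", value("Retrospective cohort"))
        assert rec.charms.values["source_of_data"].text == "Retrospective cohort"

    def test_no_information_counts_as_filled(self):
        p = _proj()
        rec = add_model(p, StudyInfo(author="X", year=2000))
        set_field(p, rec, "source_of_data", NO_INFORMATION)
        assert rec.charms.values["source_of_data"].filled

    def test_off_list_option_rejected(self):
        p = _proj()
        rec = add_model(p, StudyInfo(author="X", year=2000))
        with pytest.raises(ValidationError, match="Anecdote"):
            set_field(p, rec, "source_of_data", value("Anecdote"))

    def test_unknown_key_rejected(self):
        p = _proj()
        rec = add_model(p, StudyInfo(author="X", year=2000))
        with pytest.raises(ValidationError, match="unknown field key"):
            set_field(p, rec, "nonexistent", value("x"))


class TestSetOptions:
    def test_extended_list_validates_new_option(self):
        p = _proj()
        rec = add_model(p, StudyInfo(author="X", year=2000))
        spec = p.catalog_field("source_of_data")
        set_options(p, "source_of_data", spec.options + ("Case series",))
        set_field(p, rec, "source_of_data", value("Case series"))

    def test_orphaned_value_flagged_not_erased(self):
        p = _proj()
        rec = add_model(p, StudyInfo(author="X", year=2000))
        set_field(p, rec, "source_of_data", value("Existing registry"))
        set_options(p, "source_of_data", ("Prospective cohort", "Randomized trial"))
        assert rec.charms.values["source_of_data"].text == "Existing registry"
        issues = validate_project(p)
        orphans = [i for i in issues if "Existing registry" in i.message]
        assert orphans and orphans[0].severity == "warning"
        assert "source_of_data" in orphans[0].path

    def test_single_option_rejected(self):
        with pytest.raises(ValidationError):
            set_options(_proj(), "source_of_data", ("Only one",))

    def test_free_text_field_rejected(self):
        with pytest.raises(ValidationError, match="free-text"):
            set_options(_proj(), "enrolment_period", ("A", "B"))

    def test_duplicate_options_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            set_options(_proj(), "source_of_data", ("A", "A"))


class TestFieldValue:
    def test_states_carry_text_consistently(self):
        with pytest.raises(ValidationError):
            FieldValue(FieldState.EMPTY, "oops")
        with pytest.raises(ValidationError):
            FieldValue(FieldState.NO_INFORMATION, "oops")
        with pytest.raises(ValidationError):
            FieldValue(FieldState.VALUE, None)

    def test_render(self):
        assert FieldValue().render() == ""
        assert NO_INFORMATION.render() == "No information"
        assert value("55 (46;66)").render() == "55 (46;66)"


def test_option_list_spec_needs_two_options():
    with pytest.raises(ValidationError):
        FieldSpec("k", "K", CharmsDomain.RESULTS, InputKind.OPTION_LIST, ("one",))


def test_catalog_covers_every_reporting_column():
    """Static cross-reference: every field key the table builders consume
    exists in the default catalog."""
    consumed = {
        "source_of_data", "enrolment_period", "study_setting", "study_region",
        "modelling_method", "sample_size", "n_events", "n_missing",
        "n_candidate_predictors", "epv", "epp", "internal_validation",
        "external_validation", "discrimination", "calibration",
    }
    keys = {s.key for s in DEFAULT_FIELD_CATALOG}
    assert consumed <= keys
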