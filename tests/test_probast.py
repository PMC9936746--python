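"""Signalling answers, the rating gate, aggregation, overall judgments."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from predrev import (
    Answer,
    Judgment,
    ProbastDomain,
    StudyInfo,
    ValidationError,
    add_model,
    aggregate,
    answer_signalling,
    build_context,
    can_rate,
    new_project,
    overall,
    override_overall,
    rate,
    set_field,
    suggest_rating,
    value,
)
from predrev.probast import CONTEXT_PLACEHOLDER, validation_warnings
from predrev.schema import DEFAULT_SIGNALLING_CATALOG

L, H, U = Judgment.LOW, Judgment.HIGH, Judgment.UNCLEAR


@pytest.fixture()
def rec():
    p = new_project("t", [])
    return add_model(p, StudyInfo(author="X", year=2000))


def _answer_domain(rec, domain, answer=Answer.YES):
    for i in range(len(DEFAULT_SIGNALLING_CATALOG[domain])):
        answer_signalling(rec, domain, i, answer)


def test_default_catalog_question_counts():
    counts = {d: len(qs) for d, qs in DEFAULT_SIGNALLING_CATALOG.items()}
    assert counts == {ProbastDomain.PARTICIPANTS: 2, ProbastDomain.PREDICTORS: 3,
                      ProbastDomain.OUTCOME: 6, ProbastDomain.ANALYSIS: 9}


def test_applicability_covers_exactly_three_domains():
    assert [d for d in ProbastDomain if d.has_applicability] == [
        ProbastDomain.PARTICIPANTS, ProbastDomain.PREDICTORS, ProbastDomain.OUTCOME]


class TestSignallingAndGate:
    def test_answer_stored(self, rec):
        answer_signalling(rec, ProbastDomain.PARTICIPANTS, 0, Answer.YES)
        assert rec.probast.answers[ProbastDomain.PARTICIPANTS][0] is Answer.YES

    def test_out_of_range_index_rejected(self, rec):
        with pytest.raises(ValidationError, match="2 signalling questions"):
            answer_signalling(rec, ProbastDomain.PARTICIPANTS, 6, Answer.YES)

    def test_gate_opens_only_when_all_answered(self, rec):
        d = ProbastDomain.ANALYSIS
        for i in range(8):
            answer_signalling(rec, d, i, Answer.PROBABLY_YES)
        assert not can_rate(rec, d)
        answer_signalling(rec, d, 8, Answer.PROBABLY_YES)
        assert can_rate(rec, d)

    def test_no_information_answers_open_the_gate(self, rec):
        _answer_domain(rec, ProbastDomain.PARTICIPANTS, Answer.NO_INFORMATION)
        assert can_rate(rec, ProbastDomain.PARTICIPANTS)

    def test_rate_before_answering_rejected(self, rec):
        with pytest.raises(ValidationError, match="signalling answer"):
            rate(rec, ProbastDomain.PARTICIPANTS, L, L)

    def test_analysis_takes_no_applicability(self, rec):
        _answer_domain(rec, ProbastDomain.ANALYSIS)
        rate(rec, ProbastDomain.ANALYSIS, H)
        assert rec.probast.rob[ProbastDomain.ANALYSIS] is H
        with pytest.raises(ValidationError, match="no applicability"):
            rate(rec, ProbastDomain.ANALYSIS, H, L)

    def test_applicability_required_elsewhere(self, rec):
        _answer_domain(rec, ProbastDomain.OUTCOME)
        with pytest.raises(ValidationError, match="applicability"):
            rate(rec, ProbastDomain.OUTCOME, L)

    def test_clearing_an_answer_clears_dependent_ratings(self, rec):
        d = ProbastDomain.PARTICIPANTS
        _answer_domain(rec, d)
        rate(rec, d, L, U)
        answer_signalling(rec, d, 1, None)
        assert rec.probast.rob[d] is None
        assert rec.probast.applicability[d] is None
        assert not can_rate(rec, d)

    @settings(max_examples=60, deadline=None)
    @given(data=st.data())
    def test_ratings_never_outlive_their_answers(self, data):
        """Gating invariant under random answer/rate/clear sequences."""
        p = new_project("t", [])
        r = add_model(p, StudyInfo(author="X", year=2000))
        ops = data.draw(st.lists(st.tuples(
            st.sampled_from(list(ProbastDomain)),
            st.sampled_from(["answer", "clear", "rate"]),
            st.integers(0, 8)), max_size=40))
        for domain, op, i in ops:
            n = len(DEFAULT_SIGNALLING_CATALOG[domain])
            if op == "answer":
                answer_signalling(r, domain, i % n, Answer.YES)
            elif op == "clear":
                answer_signalling(r, domain, i % n, None)
            elif can_rate(r, domain):
                rate(r, domain, H, U if domain.has_applicability else None)
            for d in ProbastDomain:
                if r.probast.rob[d] is not None or (
                        d.has_applicability
                        and r.probast.applicability[d] is not None):
                    assert all(a is not None for a in r.probast.answers[d])


class TestAggregate:
    @pytest.mark.parametrize("judgments, expected", [
        ([H, U, L, H], H),      # any high domain dominates
        ([U, L, L, U], U),      # unclear without high
        ([L, L, L, L], L),      # uniformly low
        ([L], L),
    ])
    def test_examples(self, judgments, expected):
        assert aggregate(judgments) is expected

    def test_matches_brute_force_max_severity_over_all_combinations(self):
        """Oracle: over every 4-judgment (81) and 3-judgment (27) combination
        the rule equals max by severity LOW < UNCLEAR < HIGH."""
        for n in (4, 3):
            for combo in itertools.product([L, U, H], repeat=n):
                oracle = max(combo, key=lambda j: j.severity)
                assert aggregate(list(combo)) is oracle

    def test_permutation_invariant_and_idempotent(self):
        for combo in itertools.product([L, U, H], repeat=3):
            results = {aggregate(list(perm))
                       for perm in itertools.permutations(combo)}
            assert len(results) == 1
        for j in Judgment:
            assert aggregate([j]) is j

    def test_raising_severity_never_lowers_output(self):
        ladder = [L, U, H]
        for combo in itertools.product(ladder, repeat=3):
            base = aggregate(list(combo))
            for i, j in enumerate(combo):
                for worse in ladder[ladder.index(j) + 1:]:
                    bumped = list(combo)
                    bumped[i] = worse
                    assert aggregate(bumped).severity >= base.severity

    def test_empty_or_incomplete_rejected(self):
        with pytest.raises(ValidationError):
            aggregate([])
        with pytest.raises(ValidationError):
            aggregate([L, None, H])


class TestSuggestRating:
    @pytest.mark.parametrize("answers, expected", [
        ([Answer.YES, Answer.PROBABLY_YES], L),
        ([Answer.YES, Answer.NO], H),
        ([Answer.YES, Answer.PROBABLY_NO], H),
        ([Answer.YES, Answer.NO_INFORMATION], U),
    ])
    def test_examples(self, answers, expected):
        assert suggest_rating(answers) is expected

    def test_incomplete_rejected(self):
        with pytest.raises(ValidationError):
            suggest_rating([Answer.YES, None])


class TestOverall:
    def _rated(self, robs, apps):
        p = new_project("t", [])
        r = add_model(p, StudyInfo(author="X", year=2000))
        for d in ProbastDomain:
            _answer_domain(r, d)
        for d, rob, app in zip(ProbastDomain, robs, list(apps) + [None]):
            rate(r, d, rob, app)
        return r

    @pytest.mark.parametrize("robs, apps, expected", [
        ((L, L, L, H), (L, U, L), (H, U)),   # one high domain, one unclear app
        ((U, L, L, H), (U, L, L), (H, U)),
        ((L, L, L, L), (L, L, L), (L, L)),
    ])
    def test_examples(self, robs, apps, expected):
        assert overall(self._rated(robs, apps)) == expected

    def test_incomplete_ratings_rejected(self, rec):
        with pytest.raises(ValidationError):
            overall(rec)

    def test_auto_overall_tracks_rating_changes(self):
        r = self._rated((L, L, L, L), (L, L, L))
        assert r.probast.overall_rob is L
        rate(r, ProbastDomain.ANALYSIS, H)
        assert r.probast.overall_rob is H

    def test_manual_override_returned_and_flagged(self):
        r = self._rated((L, L, L, L), (L, L, L))
        override_overall(r, overall_rob=H)
        assert r.probast.overall_rob_override
        assert overall(r) == (H, L)
        rate(r, ProbastDomain.OUTCOME, L, L)  # override survives re-rating
        assert overall(r) == (H, L)
        override_overall(r)  # release
        assert overall(r) == (L, L)
        assert not r.probast.overall_rob_override


class TestContextTransfer:
    def test_extracted_values_transferred(self):
        p = new_project("t", [])
        r = add_model(p, StudyInfo(author="De Feo", year=2012))
        set_field(p, r, "source_of_data", value("Retrospective cohort"))
        ctx = build_context(r.charms)
        assert ctx["Source of data"] == "Retrospective cohort"

    def test_empty_record_yields_placeholders(self, rec):
        ctx = build_context(rec.charms)
        assert set(ctx.values()) == {CONTEXT_PLACEHOLDER}

    def test_deterministic(self, rec):
        assert build_context(rec.charms) == build_context(rec.charms)


def test_low_overall_without_external_validation_warns():
    p = new_project("t", [])
    r = add_model(p, StudyInfo(author="X", year=2000))
    for d in ProbastDomain:
        _answer_domain(r, d)
        rate(r, d, L, L if d.has_applicability else None)
    assert validation_warnings(r) == []
    set_field(p, r, "external_validation", value("No"))
    assert any("external" in w for w in validation_warnings(r))
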