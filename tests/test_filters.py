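"""Term-based filtering with subsumption, order-only suppression, version collapsing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comodiff import annotate_delta, diff
from comodiff.classifier import ChangeAnnotation
from comodiff.errors import UnknownTermError
from comodiff.filters import (
    PROFILES,
    FilterProfile,
    collapse_versions,
    filter_changes,
    is_order_only,
)
from comodiff.fixtures import make_version_pair


def _ann(op_id="op1", change="Update", applies="XmlAttribute", affects=(),
         reason=(), order_only=False):
    return ChangeAnnotation(op_id, change, applies,
                            affects=frozenset(affects),
                            has_reason=frozenset(reason),
                            order_only=order_only)


class TestIsOrderOnly:
    def test_parameter_reshuffle_moves_are_order_only(self):
        a, b, _ = make_version_pair("reshuffle_parameters", seed=1)
        delta = diff(a, b, "sbml")
        moves = [op for op in delta if op.kind == "Move"]
        assert moves
        assert all(is_order_only(op, "sbml") for op in moves)

    def test_non_move_operations_are_never_order_only(self, km1_docs):
        delta = diff(*km1_docs, "sbml")
        assert not any(is_order_only(op, "sbml") for op in delta)

    def test_cross_parent_move_is_not_order_only(self):
        a = ("<sbml><model id='m'><listOfReactions>"
             "<reaction id='r1'><kineticLaw><parameter id='p'/></kineticLaw></reaction>"
             "</listOfReactions><listOfParameters/></model></sbml>")
        b = ("<sbml><model id='m'><listOfReactions>"
             "<reaction id='r1'><kineticLaw/></reaction>"
             "</listOfReactions><listOfParameters><parameter id='p'/>"
             "</listOfParameters></model></sbml>")
        delta = diff(a, b, "sbml")
        moves = [op for op in delta if op.kind == "Move"]
        assert moves and not any(is_order_only(op, "sbml") for op in moves)


class TestFilterChanges:
    def test_empty_profile_keeps_everything(self):
        anns = [_ann("op1"), _ann("op2", affects={"ModelEncoding"})]
        assert filter_changes(anns, FilterProfile()) == anns

    def test_include_changed_specification_keeps_only_spec_changes(self):
        anns = [_ann("op1", affects={"ParameterSetup"}),
                _ann("op2", affects={"ModelEncoding"},
                     reason={"ChangedSpecification"}),
                _ann("op3", affects={"ModelAnnotation"})]
        kept = filter_changes(anns, FilterProfile(
            include_terms=frozenset({"ChangedSpecification"})))
        assert [a.op_id for a in kept] == ["op2"]

    def test_subsumption_keeps_parameter_setup_under_model_setup(self):
        anns = [_ann("op1", affects={"ParameterSetup"})]
        kept = filter_changes(anns, FilterProfile(
            include_terms=frozenset({"ModelSetup"})))
        assert kept == anns
        none = filter_changes(anns, FilterProfile(
            include_terms=frozenset({"ModelSetup"}), use_subsumption=False))
        assert none == []

    def test_include_target_keeps_every_change_with_affects_terms(self):
        anns = [_ann("op1", affects={"ParameterSetup"}),
                _ann("op2", affects={"ModelAnnotation"}),
                _ann("op3", affects=set())]
        kept = filter_changes(anns, FilterProfile(include_terms=frozenset({"Target"})))
        assert [a.op_id for a in kept] == ["op1", "op2"]

    def test_exclusion_beats_inclusion(self):
        anns = [_ann("op1", affects={"ParameterSetup", "ModelAnnotation"})]
        kept = filter_changes(anns, FilterProfile(
            include_terms=frozenset({"ModelSetup"}),
            exclude_terms=frozenset({"ModelAnnotation"})))
        assert kept == []

    def test_drop_order_only(self):
        anns = [_ann("op1", change="Move", applies="XmlNode", order_only=True),
                _ann("op2")]
        kept = filter_changes(anns, FilterProfile(drop_order_only=True))
        assert [a.op_id for a in kept] == ["op2"]

    def test_unknown_profile_term_raises(self):
        with pytest.raises(UnknownTermError):
            filter_changes([], FilterProfile(include_terms=frozenset({"Nope"})))

    def test_overlapping_include_exclude_rejected(self):
        with pytest.raises(ValueError):
            FilterProfile(include_terms=frozenset({"Target"}),
                          exclude_terms=frozenset({"Target"}))

    def test_idempotent(self):
        anns = [_ann("op1", affects={"ParameterSetup"}), _ann("op2")]
        profile = FilterProfile(include_terms=frozenset({"ModelSetup"}))
        once = filter_changes(anns, profile)
        assert filter_changes(once, profile) == once

    _TERMS = ["ParameterSetup", "ModelSetup", "ModelAnnotation", "ModelEncoding",
              "KineticsDefinition", "Target", "Typo", "Correction"]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(inc=st.frozensets(st.sampled_from(_TERMS), max_size=3),
           extra=st.sampled_from(_TERMS))
    def test_enlarging_include_set_is_monotone(self, inc, extra):
        anns = [_ann("op1", affects={"ParameterSetup"}),
                _ann("op2", affects={"ModelAnnotation"}),
                _ann("op3", affects={"KineticsDefinition"}, reason={"Typo"})]
        small = {a.op_id for a in filter_changes(anns, FilterProfile(include_terms=inc))}
        big = {a.op_id for a in filter_changes(
            anns, FilterProfile(include_terms=inc | {extra}))}
        if inc:  # an empty include set means "keep everything"
            assert small <= big

    def test_named_profiles(self):
        anns = [_ann("op1", affects={"ModelAnnotation"}),
                _ann("op2", change="Move", applies="XmlNode", order_only=True),
                _ann("op3", affects={"ParameterSetup"})]
        modeller = filter_changes(anns, PROFILES["modeller"])
        curator = filter_changes(anns, PROFILES["curator"])
        assert [a.op_id for a in modeller] == ["op3"]
        assert [a.op_id for a in curator] == ["op1", "op3"]


class TestCollapseVersions:
    def test_only_relevant_versions_survive(self):
        series = [
            [_ann("op1", affects={"ModelEncoding"})],           # spec bump only
            [],                                                  # no changes
            [_ann("op1", affects={"ModelEncoding"})],
            [_ann("op1", affects={"ParameterSetup"})],           # the real change
        ]
        profile = FilterProfile(exclude_terms=frozenset({"ModelEncoding"}))
        assert collapse_versions(series, profile) == [3]

    def test_all_empty_series_collapses_to_nothing(self):
        assert collapse_versions([[], [], []], FilterProfile()) == []

    def test_empty_profile_keeps_all_non_empty_versions(self):
        series = [[], [_ann("op1")], [], [_ann("op1"), _ann("op2")]]
        assert collapse_versions(series, FilterProfile()) == [1, 3]
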