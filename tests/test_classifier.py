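"""Automatic XmlEntity/Target classification and trigger inference."""

import pytest

from comodiff import annotate_delta, classify_entity, classify_target, diff, infer_triggers
from comodiff.errors import RangeViolationError, UnknownDialectError, UnknownTermError
from comodiff.fixtures import make_version_pair
from comodiff.xml_diff import ChangeOperation, Delta, XmlAddress


def _op(kind="Update", entity="XmlAttribute", path="sbml[1]/model[1]",
        attribute=None, text=False, **kw):
    addr = XmlAddress(path, attribute=attribute, text=text)
    side = {"address_a": addr} if kind in ("Deletion", "Update", "Move") else {"address_b": addr}
    if kind == "Update":
        kw.setdefault("old_value", "0")
        kw.setdefault("new_value", "1")
        kw.setdefault("address_b", addr)
    if kind == "Move":
        kw.setdefault("address_b", addr)
    return ChangeOperation("op1", kind, entity, **side, **kw)


class TestClassifyEntity:
    def test_attribute_text_and_node_operations(self):
        assert classify_entity(_op(attribute="value")) == "XmlAttribute"
        assert classify_entity(_op(kind="Deletion", entity="XmlNode",
                                   path="sbml[1]/model[1]/listOfSpecies[1]/species[1]")) == "XmlNode"
        assert classify_entity(_op(text=True, entity="XmlText")) == "XmlText"


class TestClassifyTarget:
    @pytest.mark.parametrize("path,attribute,expected", [
        ("sbml[1]/model[1]/listOfParameters[1]/parameter[1]", "value",
         {"ParameterSetup"}),
        ("sbml[1]", "xmlns", {"ModelEncoding"}),
        ("sbml[1]", "level", {"ModelEncoding"}),
        ("sbml[1]/model[1]/listOfSpecies[1]/species[2]", "name",
         {"EntityName", "ReactionNetworkDefinition"}),
        ("sbml[1]/model[1]/listOfSpecies[1]/species[2]", "id",
         {"EntityIdentifier", "ReactionNetworkDefinition"}),
        ("sbml[1]/model[1]/listOfReactions[1]/reaction[1]/kineticLaw[1]/math[1]/apply[1]",
         None, {"KineticsDefinition"}),
        ("sbml[1]/model[1]/annotation[1]/RDF[1]/Description[1]", None,
         {"ModelAnnotation"}),
        ("sbml[1]/model[1]", "name", {"EntityName"}),
        ("sbml[1]/model[1]", None, set()),
    ])
    def test_sbml_rule_table(self, path, attribute, expected):
        op = _op(path=path, attribute=attribute,
                 entity="XmlAttribute" if attribute else "XmlNode",
                 kind="Update" if attribute else "Deletion")
        assert classify_target(op, "sbml") == frozenset(expected)

    @pytest.mark.parametrize("path,attribute,expected", [
        ("model[1]/component[1]/variable[2]", "initial_value", {"ParameterSetup"}),
        ("model[1]/component[1]/math[1]/apply[1]", None, {"KineticsDefinition"}),
        ("model[1]/component[1]", None, {"ModelDefinition"}),
        ("model[1]/RDF[1]/Description[1]", None, {"ModelAnnotation"}),
        ("model[1]", "xmlns", {"ModelEncoding"}),
    ])
    def test_cellml_rule_table(self, path, attribute, expected):
        op = _op(path=path, attribute=attribute,
                 entity="XmlAttribute" if attribute else "XmlNode",
                 kind="Update" if attribute else "Deletion")
        assert classify_target(op, "cellml") == frozenset(expected)

    def test_unknown_dialect_is_rejected(self):
        with pytest.raises(UnknownDialectError):
            classify_target(_op(attribute="value"), "matlab")

    def test_classification_is_deterministic(self, fixture_deltas):
        for key, delta in fixture_deltas.items():
            once = [classify_target(op, "sbml") for op in delta]
            again = [classify_target(op, "sbml") for op in delta]
            assert once == again


class TestInferTriggers:
    def test_reaction_deletion_triggers_kinetic_law_deletion(self):
        a, b, _ = make_version_pair("reaction_delete", seed=1)
        delta = diff(a, b, "sbml")
        by_tag = {}
        for op in delta:
            if op.entity_kind == "XmlNode":
                by_tag.setdefault(op.address.tags[-1], []).append(op)
        (kl,) = by_tag["kineticLaw"]
        (rx,) = by_tag["reaction"]
        assert kl.triggered_by == {rx.op_id}

    def test_singleton_update_has_no_triggers(self, km1_docs):
        delta = infer_triggers(diff(*km1_docs, "sbml"))
        assert all(not op.triggered_by for op in delta)

    def test_deleted_species_attributes_point_at_node_deletion(self):
        a, b, _ = make_version_pair("species_delete", seed=2)
        delta = diff(a, b, "sbml")
        node = next(o for o in delta
                    if o.entity_kind == "XmlNode" and o.address.tags[-1] == "species")
        attr_ops = [o for o in delta if o.entity_kind == "XmlAttribute"
                    and o.address.tags[-1] == "species"]
        assert len(attr_ops) == 4
        assert all(o.triggered_by == {node.op_id} for o in attr_ops)

    def test_trigger_graph_is_acyclic_with_topological_order(self, fixture_deltas):
        import networkx as nx
        for delta in fixture_deltas.values():
            infer_triggers(delta)
            g = nx.DiGraph()
            g.add_nodes_from(op.op_id for op in delta)
            g.add_edges_from((op.op_id, t) for op in delta for t in op.triggered_by)
            assert list(nx.topological_sort(g))  # raises on cycles

    def test_idempotent(self, km1_docs):
        delta = diff(*km1_docs, "sbml")
        once = [set(op.triggered_by) for op in infer_triggers(delta)]
        twice = [set(op.triggered_by) for op in infer_triggers(delta)]
        assert once == twice


class TestAnnotateDelta:
    def test_km1_update_with_user_intention_and_reason(self, km1_docs):
        delta = diff(*km1_docs, "sbml")
        user = {delta.operations[0].op_id: {
            "hasIntention": ["Correction"],
            "hasReason": ["MismatchWithPublication"]}}
        (ann,) = annotate_delta(delta, "sbml", user_annotations=user)
        assert ann.change_term == "Update"
        assert ann.applies_to == "XmlAttribute"
        assert ann.affects == {"ParameterSetup"}
        assert ann.has_intention == {"Correction"}
        assert ann.has_reason == {"MismatchWithPublication"}

    def test_empty_delta_yields_no_annotations(self):
        assert annotate_delta(Delta(), "sbml") == []

    def test_range_violation_for_target_term_as_intention(self, km1_docs):
        delta = diff(*km1_docs, "sbml")
        user = {delta.operations[0].op_id: {"hasIntention": ["ParameterSetup"]}}
        with pytest.raises(RangeViolationError, match="hasIntention"):
            annotate_delta(delta, "sbml", user_annotations=user)

    def test_unknown_user_term_is_rejected(self, km1_docs):
        delta = diff(*km1_docs, "sbml")
        user = {delta.operations[0].op_id: {"hasReason": ["BecauseISaidSo"]}}
        with pytest.raises(UnknownTermError):
            annotate_delta(delta, "sbml", user_annotations=user)

    def test_model_behaviour_accepted_only_from_user(self, km1_docs):
        delta = diff(*km1_docs, "sbml")
        auto = annotate_delta(delta, "sbml")
        assert all("ModelBehaviour" not in a.affects for a in auto)
        user = {delta.operations[0].op_id: {"affects": ["ModelBehaviour"]}}
        (ann,) = annotate_delta(delta, "sbml", user_annotations=user)
        assert "ModelBehaviour" in ann.affects

    def test_all_annotations_respect_property_ranges(self, voc, fixture_deltas):
        for delta in fixture_deltas.values():
            for ann in annotate_delta(delta, "sbml"):
                assert voc.is_a(ann.change_term, "Change")
                assert voc.is_a(ann.applies_to, "XmlEntity")
                for t in ann.affects:
                    assert voc.is_a(t, "Target")
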