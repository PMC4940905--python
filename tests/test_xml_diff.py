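"""Tree matching, delta computation, patching and canonicalization."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comodiff.errors import (
    DeltaSchemaError,
    MalformedDocumentError,
    UnresolvableAddressError,
)
from comodiff.xml_diff import (
    ChangeOperation,
    Delta,
    XmlAddress,
    canonicalize,
    compute_delta,
    diff,
    documents_equal,
    match_trees,
    parse_delta,
    parse_document,
    patch,
    serialize_delta,
)


class TestMatchTrees:
    def test_identical_documents_match_every_node(self):
        doc = ("<sbml><model id='m'><listOfSpecies>"
               "<species id='s1'/><species id='s2'/></listOfSpecies></model></sbml>")
        m = match_trees(doc, doc, "sbml")
        n_nodes = sum(1 for _ in parse_document(doc).iter())
        assert len(m) == n_nodes

    def test_id_anchored_match_survives_value_change(self, km1_docs):
        a, b = km1_docs
        m = match_trees(a, b, "sbml")
        pa = [x for x, _ in m.pairs()]
        assert any(x.get("id") == "Km1" for x in pa)

    def test_disjoint_documents_do_not_match(self):
        a = "<alpha><x id='1'/></alpha>"
        b = "<beta><y id='2'/></beta>"
        m = match_trees(a, b, "generic-xml")
        assert len(m) == 0  # different root tags: nothing anchors

    def test_malformed_document_raises(self):
        with pytest.raises(MalformedDocumentError):
            match_trees("<unclosed>", "<ok/>", "generic-xml")


class TestComputeDelta:
    def test_identical_documents_give_empty_delta(self, fixture_pairs):
        for (mut, seed), (a, _, _) in fixture_pairs.items():
            assert diff(a, a, "sbml").is_empty

    def test_km1_value_update_is_single_attribute_update(self, km1_docs):
        a, b = km1_docs
        delta = diff(a, b, "sbml")
        assert len(delta) == 1
        (op,) = delta.operations
        assert op.kind == "Update"
        assert op.entity_kind == "XmlAttribute"
        assert op.old_value == "23.24"
        assert op.new_value == "23.42"
        assert op.address_a.attribute == "value"

    def test_inserted_node_attributes_are_triggered_by_node_insertion(self):
        a = "<sbml><model id='m'><listOfSpecies/></model></sbml>"
        b = ("<sbml><model id='m'><listOfSpecies>"
             "<species id='s1' name='X' compartment='c'/>"
             "</listOfSpecies></model></sbml>")
        delta = diff(a, b, "sbml")
        node_ops = [o for o in delta if o.entity_kind == "XmlNode"]
        attr_ops = [o for o in delta if o.entity_kind == "XmlAttribute"]
        assert len(node_ops) == 1 and node_ops[0].kind == "Insertion"
        assert len(attr_ops) == 3
        assert all(o.triggered_by == {node_ops[0].op_id} for o in attr_ops)

    def test_symmetry_of_magnitude_for_moveless_pairs(self, fixture_pairs):
        swap = {"Insertion": "Deletion", "Deletion": "Insertion",
                "Update": "Update", "Move": "Move"}
        for (mut, seed), (a, b, _) in fixture_pairs.items():
            if mut == "reshuffle_parameters":
                continue
            fwd = diff(a, b, "sbml")
            rev = diff(b, a, "sbml")
            assert sorted(swap[o.kind] for o in fwd) == sorted(o.kind for o in rev), \
                (mut, seed)


class TestPatch:
    def test_empty_delta_is_identity(self, km1_docs):
        a, _ = km1_docs
        assert documents_equal(patch(a, Delta()), a)

    def test_round_trip_over_all_fixture_pairs(self, fixture_pairs, fixture_deltas):
        for key, (a, b, _) in fixture_pairs.items():
            assert documents_equal(patch(a, fixture_deltas[key]), b), key

    def test_round_trip_after_delta_serialization(self, fixture_pairs):
        for key, (a, b, _) in fixture_pairs.items():
            delta = parse_delta(serialize_delta(diff(a, b, "sbml")))
            assert documents_equal(patch(a, delta), b), key

    def test_unresolvable_address_names_the_operation(self, km1_docs):
        a, _ = km1_docs
        bad = Delta(operations=[ChangeOperation(
            "op9", "Deletion", "XmlNode",
            address_a=XmlAddress("sbml[1]/model[1]/listOfSpecies[7]"))])
        with pytest.raises(UnresolvableAddressError, match="op9"):
            patch(a, bad)

    def test_composed_mutations_round_trip(self):
        from comodiff.fixtures import MutationSpec, apply_mutation, make_base_model
        base = make_base_model("sbml", 4, 2, seed=3)
        doc = base
        for m in ("parameter_value_update", "species_insert", "reaction_delete",
                  "reshuffle_parameters"):
            doc, _ = apply_mutation(doc, MutationSpec(m), seed=3)
        delta = diff(base, doc, "sbml")
        assert documents_equal(patch(base, delta), doc)


class TestCanonicalize:
    def test_attribute_order_is_insignificant(self):
        assert canonicalize("<a x='1' y='2'/>") == canonicalize("<a y='2' x='1'/>")

    def test_value_differences_are_significant(self):
        assert canonicalize("<a x='1'/>") != canonicalize("<a x='2'/>")

    def test_namespace_prefixes_are_normalized(self):
        a = "<p:a xmlns:p='urn:u'><p:b/></p:a>"
        b = "<q:a xmlns:q='urn:u'><q:b/></q:a>"
        assert canonicalize(a) == canonicalize(b)

    def test_idempotence_on_fixtures(self, fixture_pairs):
        for a, b, _ in fixture_pairs.values():
            for doc in (a, b):
                c = canonicalize(doc)
                assert canonicalize(c) == c

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.sampled_from("abcd"),
                  st.text(alphabet="xy 1", min_size=0, max_size=4)),
        min_size=0, max_size=6))
    def test_idempotence_on_random_small_trees(self, children):
        parts = "".join(f"<{t}>{txt}</{t}>" for t, txt in children)
        doc = f"<root>{parts}</root>"
        c = canonicalize(doc)
        assert canonicalize(c) == c


class TestDeltaSerialization:
    def test_km1_diff_xml_carries_old_and_new_value(self, km1_docs):
        a, b = km1_docs
        text = serialize_delta(diff(a, b, "sbml"))
        root = parse_document(text)
        ops = list(root)
        assert len(ops) == 1
        assert ops[0].get("oldValue") == "23.24"
        assert ops[0].get("newValue") == "23.42"

    def test_empty_delta_serializes_without_operations(self):
        root = parse_document(serialize_delta(Delta()))
        assert len(root) == 0

    def test_round_trip_equality_over_fixtures(self, fixture_deltas):
        for key, delta in fixture_deltas.items():
            assert parse_delta(serialize_delta(delta)) == delta, key

    def test_deterministic_serialization(self, fixture_pairs):
        for a, b, _ in fixture_pairs.values():
            assert serialize_delta(diff(a, b, "sbml")) == \
                serialize_delta(diff(a, b, "sbml"))

    def test_schema_violations_are_listed(self):
        bad = "<modelDelta><operation id='op1' kind='Teleport' entity='XmlNode'/></modelDelta>"
        with pytest.raises(DeltaSchemaError, match="Teleport"):
            parse_delta(bad)

    def test_address_string_forms(self):
        for s in ("a[1]/b[2]", "a[1]/b[2]/@value", "a[1]/#text"):
            assert str(XmlAddress.parse(s)) == s
        with pytest.raises(ValueError):
            XmlAddress("a[1]", attribute="x", text=True)
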