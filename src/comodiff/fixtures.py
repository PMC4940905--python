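"""Synthetic model version pairs with known ground-truth annotations.

Real model repositories show a recurring set of change classes: parameter
value corrections, typo fixes in entity names, species/reactions added or
removed, format-specification upgrades, annotation-scheme edits and pure
element reshuffles written by round-tripping tools.  This module generates
small but structurally complete SBML (Level 2 Version 4) or CellML (1.0)
documents and applies scripted mutations of exactly those classes, each
returning the mutated document together with the annotations the pipeline
is expected to produce — the ground truth the test suite checks against.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from lxml import etree

from .classifier import ChangeAnnotation, classify_entity, classify_target
from .errors import InvalidCountError, TargetMissingError
from .xml_diff import Delta, _element_children, local_name, parse_document

SBML_L2V4_NS = "http://www.sbml.org/sbml/level2/version4"
SBML_L3V1_NS = "http://www.sbml.org/sbml/level3/version1/core"
CELLML_10_NS = "http://www.cellml.org/cellml/1.0#"
CELLML_11_NS = "http://www.cellml.org/cellml/1.1#"
CMETA_NS = "http://www.cellml.org/metadata/1.0#"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"

#: Species names; the first is deliberately misspelt so that the typo_rename
#: mutation has its canonical target.
_SPECIES_NAMES = ("Gulcose", "Fructose", "Pyruvate", "ATP", "ADP", "NADH",
                  "Lactate", "Citrate", "Oxaloacetate", "AcetylCoA")

MUTATION_NAMES = (
    "parameter_value_update", "typo_rename", "species_insert", "species_delete",
    "reaction_delete", "spec_upgrade", "annotation_edit", "reshuffle_parameters",
)


@dataclass
class MutationSpec:
    """A scripted mutation: its name and mutation-specific parameters."""

    name: str
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ExpectedChange:
    """A (change kind, XmlEntity, Target terms) triple the pipeline must produce."""

    change_term: str
    applies_to: str
    affects: frozenset[str] = frozenset()
    order_only: bool = False


@dataclass(frozen=True)
class ExpectedTrigger:
    """Every op on a ``triggered_tag`` entity must be triggered by an op on
    a ``trigger_tag`` node."""

    triggered_tag: str
    triggered_entity: str
    trigger_tag: str


@dataclass
class Expectation:
    """Ground truth carried alongside a generated version pair."""

    changes: tuple[ExpectedChange, ...] = ()
    triggers: tuple[ExpectedTrigger, ...] = ()
    intention: frozenset[str] = frozenset()
    reason: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# base model generation

def _serialize(root: etree._Element) -> str:
    etree.indent(root, space="  ")
    return etree.tostring(root, encoding="unicode", pretty_print=True)


def _rdf_annotation(parent: etree._Element, about: str, go_id: int) -> None:
    annotation = etree.SubElement(parent, f"{{{parent.nsmap[None]}}}annotation") \
        if parent.nsmap.get(None) else etree.SubElement(parent, "annotation")
    rdf = etree.SubElement(annotation, f"{{{RDF_NS}}}RDF",
                           nsmap={"rdf": RDF_NS, "bqbiol": BQBIOL_NS})
    desc = etree.SubElement(rdf, f"{{{RDF_NS}}}Description")
    desc.set(f"{{{RDF_NS}}}about", about)
    link = etree.SubElement(desc, f"{{{BQBIOL_NS}}}is")
    link.set(f"{{{RDF_NS}}}resource", f"urn:miriam:obo.go:GO%3A{go_id:07d}")


def _make_sbml(n_species: int, n_reactions: int, rng: random.Random) -> str:
    ns = SBML_L2V4_NS
    root = etree.Element(f"{{{ns}}}sbml", nsmap={None: ns})
    root.set("level", "2")
    root.set("version", "4")
    model = etree.SubElement(root, f"{{{ns}}}model")
    model.set("id", "synthetic_model")
    model.set("name", "synthetic kinetic model")
    _rdf_annotation(model, "#synthetic_model", rng.randrange(1, 10 ** 7))

    loc = etree.SubElement(model, f"{{{ns}}}listOfCompartments")
    comp = etree.SubElement(loc, f"{{{ns}}}compartment")
    comp.set("id", "cell")
    comp.set("size", "1")

    los = etree.SubElement(model, f"{{{ns}}}listOfSpecies")
    for i in range(n_species):
        sp = etree.SubElement(los, f"{{{ns}}}species")
        sp.set("id", f"S{i + 1}")
        name = _SPECIES_NAMES[i] if i < len(_SPECIES_NAMES) else f"Species{i + 1}"
        sp.set("name", name)
        sp.set("compartment", "cell")
        sp.set("initialConcentration", f"{rng.uniform(0.1, 10.0):.3f}")

    lop = etree.SubElement(model, f"{{{ns}}}listOfParameters")
    n_pairs = max(n_reactions, 1)
    for j in range(n_pairs):
        km = etree.SubElement(lop, f"{{{ns}}}parameter")
        km.set("id", f"Km{j + 1}")
        km.set("value", f"{rng.uniform(1.0, 50.0):.2f}")
        km.set("units", "molesperlitre")
        vmax = etree.SubElement(lop, f"{{{ns}}}parameter")
        vmax.set("id", f"Vmax{j + 1}")
        vmax.set("value", f"{rng.uniform(0.1, 5.0):.2f}")

    lor = etree.SubElement(model, f"{{{ns}}}listOfReactions")
    for j in range(n_reactions):
        reactant = f"S{rng.randrange(n_species) + 1}"
        product = f"S{rng.randrange(n_species) + 1}"
        rx = etree.SubElement(lor, f"{{{ns}}}reaction")
        rx.set("id", f"R{j + 1}")
        rx.set("reversible", "false")
        lre = etree.SubElement(rx, f"{{{ns}}}listOfReactants")
        sr = etree.SubElement(lre, f"{{{ns}}}speciesReference")
        sr.set("species", reactant)
        lpr = etree.SubElement(rx, f"{{{ns}}}listOfProducts")
        sr = etree.SubElement(lpr, f"{{{ns}}}speciesReference")
        sr.set("species", product)
        kl = etree.SubElement(rx, f"{{{ns}}}kineticLaw")
        math = etree.SubElement(kl, f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})
        apply_div = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
        etree.SubElement(apply_div, f"{{{MATHML_NS}}}divide")
        num = etree.SubElement(apply_div, f"{{{MATHML_NS}}}apply")
        etree.SubElement(num, f"{{{MATHML_NS}}}times")
        etree.SubElement(num, f"{{{MATHML_NS}}}ci").text = f"Vmax{j + 1}"
        etree.SubElement(num, f"{{{MATHML_NS}}}ci").text = reactant
        den = etree.SubElement(apply_div, f"{{{MATHML_NS}}}apply")
        etree.SubElement(den, f"{{{MATHML_NS}}}plus")
        etree.SubElement(den, f"{{{MATHML_NS}}}ci").text = f"Km{j + 1}"
        etree.SubElement(den, f"{{{MATHML_NS}}}ci").text = reactant
    return _serialize(root)


def _make_cellml(n_species: int, n_reactions: int, rng: random.Random) -> str:
    ns = CELLML_10_NS
    root = etree.Element(f"{{{ns}}}model", nsmap={None: ns, "cmeta": CMETA_NS})
    root.set("name", "synthetic_model")
    root.set(f"{{{CMETA_NS}}}id", "synthetic_model")
    rdf = etree.SubElement(root, f"{{{RDF_NS}}}RDF",
                           nsmap={"rdf": RDF_NS, "bqbiol": BQBIOL_NS})
    desc = etree.SubElement(rdf, f"{{{RDF_NS}}}Description")
    desc.set(f"{{{RDF_NS}}}about", "#synthetic_model")
    link = etree.SubElement(desc, f"{{{BQBIOL_NS}}}is")
    link.set(f"{{{RDF_NS}}}resource",
             f"urn:miriam:obo.go:GO%3A{rng.randrange(1, 10 ** 7):07d}")
    main = etree.SubElement(root, f"{{{ns}}}component")
    main.set("name", "main")
    for i in range(n_species):
        var = etree.SubElement(main, f"{{{ns}}}variable")
        var.set("name", f"x{i + 1}")
        var.set("units", "dimensionless")
        var.set("initial_value", f"{rng.uniform(0.1, 10.0):.3f}")
    for j in range(n_reactions):
        km = etree.SubElement(main, f"{{{ns}}}variable")
        km.set("name", f"Km{j + 1}")
        km.set("units", "dimensionless")
        km.set("initial_value", f"{rng.uniform(1.0, 50.0):.2f}")
        math = etree.SubElement(main, f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})
        apply_eq = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
        etree.SubElement(apply_eq, f"{{{MATHML_NS}}}eq")
        etree.SubElement(apply_eq, f"{{{MATHML_NS}}}ci").text = f"rate{j + 1}"
        etree.SubElement(apply_eq, f"{{{MATHML_NS}}}ci").text = f"Km{j + 1}"
    return _serialize(root)


def make_base_model(dialect: str = "sbml", n_species: int = 4,
                    n_reactions: int = 2, seed: int = 1) -> str:
    """Deterministic (seeded) synthetic model document as XML text.

    SBML documents are Level 2 Version 4 core with species, parameters,
    reactions with kinetic laws and an RDF annotation block; CellML
    documents are 1.0 with variables, math and an RDF block.
    """
    if n_species < 0 or n_reactions < 0:
        raise InvalidCountError("entity counts must be non-negative")
    if n_reactions > 0 and n_species < 1:
        raise InvalidCountError("reactions require at least one species")
    rng = random.Random(seed)
    if dialect == "sbml":
        return _make_sbml(n_species, n_reactions, rng)
    if dialect == "cellml":
        return _make_cellml(n_species, n_reactions, rng)
    raise InvalidCountError(f"no generator for dialect {dialect!r}")


# ---------------------------------------------------------------------------
# scripted mutations

def _find_one(root, tag: str, attr: Optional[str] = None,
              value: Optional[str] = None):
    for el in root.iter():
        if not isinstance(el.tag, str) or local_name(el.tag) != tag:
            continue
        if attr is None or el.get(attr) == value:
            return el
    return None


def _mut_parameter_value_update(root, params, rng) -> Expectation:
    pid = params.get("parameter_id", "Km1")
    el = _find_one(root, "parameter", "id", pid)
    attr = "value"
    if el is None:  # CellML: a variable's initial value plays the same role
        el = _find_one(root, "variable", "name", pid)
        attr = "initial_value"
    if el is None or el.get(attr) is None:
        raise TargetMissingError(f"no parameter {pid!r} with a value")
    old = el.get(attr)
    new = params.get("new_value")
    if new is None:
        new = f"{float(old) * rng.uniform(1.05, 1.5) + 0.01:.2f}"
        if new == old:
            new = f"{float(old) + 1.0:.2f}"
    el.set(attr, new)
    return Expectation(
        changes=(ExpectedChange("Update", "XmlAttribute",
                                frozenset({"ParameterSetup"})),),
        intention=frozenset({"Correction"}),
        reason=frozenset({"MismatchWithPublication"}),
    )


def _mut_typo_rename(root, params, rng) -> Expectation:
    old = params.get("old_name", "Gulcose")
    new = params.get("new_name", "Glucose")
    el = _find_one(root, "species", "name", old)
    if el is None:
        for cand in root.iter():
            if isinstance(cand.tag, str) and cand.get("name") == old:
                el = cand
                break
    if el is None:
        raise TargetMissingError(f"no element named {old!r}")
    el.set("name", new)
    return Expectation(
        changes=(ExpectedChange("Update", "XmlAttribute",
                                frozenset({"EntityName"})),),
        intention=frozenset({"Correction"}),
        reason=frozenset({"Typo"}),
    )


def _mut_species_insert(root, params, rng) -> Expectation:
    los = _find_one(root, "listOfSpecies")
    if los is None:
        raise TargetMissingError("no listOfSpecies container")
    ns = los.nsmap.get(None)
    sp = etree.SubElement(los, f"{{{ns}}}species" if ns else "species")
    sp.set("id", params.get("species_id", f"S_new{rng.randrange(10, 100)}"))
    sp.set("name", params.get("name", "Glyceraldehyde"))
    sp.set("compartment", "cell")
    sp.set("initialConcentration", f"{rng.uniform(0.1, 10.0):.3f}")
    return Expectation(
        changes=(ExpectedChange("Insertion", "XmlNode",
                                frozenset({"ReactionNetworkDefinition"})),),
        triggers=(ExpectedTrigger("species", "XmlAttribute", "species"),),
    )


def _pick_species(root, params):
    sid = params.get("species_id")
    if sid is not None:
        el = _find_one(root, "species", "id", sid)
        if el is None:
            raise TargetMissingError(f"no species {sid!r}")
        return el
    referenced = {el.get("species") for el in root.iter()
                  if isinstance(el.tag, str)
                  and local_name(el.tag) == "speciesReference"}
    candidates = [el for el in root.iter()
                  if isinstance(el.tag, str) and local_name(el.tag) == "species"]
    if not candidates:
        raise TargetMissingError("document has no species")
    for el in candidates:
        if el.get("id") not in referenced:
            return el
    return candidates[-1]


def _mut_species_delete(root, params, rng) -> Expectation:
    el = _pick_species(root, params)
    el.getparent().remove(el)
    return Expectation(
        changes=(ExpectedChange("Deletion", "XmlNode",
                                frozenset({"ReactionNetworkDefinition"})),),
        triggers=(ExpectedTrigger("species", "XmlAttribute", "species"),),
    )


def _mut_reaction_delete(root, params, rng) -> Expectation:
    rid = params.get("reaction_id")
    el = (_find_one(root, "reaction", "id", rid) if rid
          else _find_one(root, "reaction"))
    if el is None:
        raise TargetMissingError(f"no reaction {rid!r}" if rid else "no reaction")
    el.getparent().remove(el)
    return Expectation(
        changes=(ExpectedChange("Deletion", "XmlNode",
                                frozenset({"ReactionNetworkDefinition"})),
                 ExpectedChange("Deletion", "XmlNode",
                                frozenset({"KineticsDefinition"}))),
        triggers=(ExpectedTrigger("kineticLaw", "XmlNode", "reaction"),),
    )


_SPEC_UPGRADES = {SBML_L2V4_NS: SBML_L3V1_NS, CELLML_10_NS: CELLML_11_NS}


def _mut_spec_upgrade(root, params, rng) -> Expectation:
    old_ns = root.nsmap.get(None)
    new_ns = params.get("new_namespace", _SPEC_UPGRADES.get(old_ns))
    if old_ns is None or new_ns is None:
        raise TargetMissingError(f"no specification upgrade for namespace {old_ns!r}")
    for el in root.iter():
        if isinstance(el.tag, str) and el.tag.startswith(f"{{{old_ns}}}"):
            el.tag = f"{{{new_ns}}}{local_name(el.tag)}"
    if root.get("level") is not None:
        root.set("level", "3")
        root.set("version", "1")
    # rebuild the root so the new namespace is declared as the default,
    # the way format-upgrading tools serialize it
    nsmap = {p: u for p, u in root.nsmap.items() if u != old_ns and p is not None}
    nsmap[None] = new_ns
    new_root = etree.Element(root.tag, nsmap=nsmap)
    for k, v in root.attrib.items():
        new_root.set(k, v)
    new_root.text = root.text
    for c in list(root):
        new_root.append(c)
    etree.cleanup_namespaces(new_root)  # drop redundant auto-added prefixes
    expectation = Expectation(
        changes=(ExpectedChange("Update", "XmlAttribute",
                                frozenset({"ModelEncoding"})),),
        reason=frozenset({"ChangedSpecification"}),
    )
    return expectation, new_root


def _mut_annotation_edit(root, params, rng) -> Expectation:
    el = None
    for cand in root.iter():
        if isinstance(cand.tag, str) and cand.get(f"{{{RDF_NS}}}resource"):
            el = cand
            break
    if el is None:
        raise TargetMissingError("no RDF resource link to edit")
    el.set(f"{{{RDF_NS}}}resource",
           params.get("new_resource",
                      f"urn:miriam:obo.go:GO%3A{rng.randrange(1, 10 ** 7):07d}"))
    return Expectation(
        changes=(ExpectedChange("Update", "XmlAttribute",
                                frozenset({"ModelAnnotation"})),),
    )


def _mut_reshuffle_parameters(root, params, rng) -> Expectation:
    lop = _find_one(root, "listOfParameters")
    if lop is None or len(_element_children(lop)) < 2:
        raise TargetMissingError("need a listOfParameters with >= 2 entries")
    children = _element_children(lop)
    perm = list(range(len(children)))
    rng.shuffle(perm)
    if perm == sorted(perm):
        perm = perm[1:] + perm[:1]
    for c in children:
        lop.remove(c)
    for i in perm:
        lop.append(children[i])
    return Expectation(
        changes=(ExpectedChange("Move", "XmlNode", frozenset(), order_only=True),),
    )


_MUTATIONS = {
    "parameter_value_update": _mut_parameter_value_update,
    "typo_rename": _mut_typo_rename,
    "species_insert": _mut_species_insert,
    "species_delete": _mut_species_delete,
    "reaction_delete": _mut_reaction_delete,
    "spec_upgrade": _mut_spec_upgrade,
    "annotation_edit": _mut_annotation_edit,
    "reshuffle_parameters": _mut_reshuffle_parameters,
}


def apply_mutation(doc: str, spec: MutationSpec, seed: int = 1,
                   ) -> tuple[str, Expectation]:
    """Apply one scripted mutation; returns (mutated document, ground truth)."""
    if spec.name not in _MUTATIONS:
        raise TargetMissingError(f"unknown mutation {spec.name!r}")
    rng = random.Random(f"{seed}:{spec.name}")
    root = parse_document(doc)
    result = _MUTATIONS[spec.name](root, spec.params, rng)
    if isinstance(result, tuple):  # mutation replaced the root element
        expectation, root = result
    else:
        expectation = result
    return _serialize(root), expectation


def make_version_pair(mutation: str, seed: int = 1, dialect: str = "sbml",
                      n_species: int = 4, n_reactions: int = 2,
                      params: Optional[dict] = None,
                      ) -> tuple[str, str, Expectation]:
    """Generate a base model and its mutated successor with ground truth."""
    base = make_base_model(dialect, n_species, n_reactions, seed)
    mutated, expectation = apply_mutation(base, MutationSpec(mutation, params or {}),
                                          seed)
    return base, mutated, expectation


# ---------------------------------------------------------------------------
# ground-truth checking

def suggest_user_annotations(delta: Delta, dialect: str,
                             expectation: Expectation) -> dict[str, dict]:
    """User-annotation map (intention/reason) for the operations that realise
    the expectation's primary changes — what a curator would record."""
    if not (expectation.intention or expectation.reason):
        return {}
    out: dict[str, dict] = {}
    for op in delta.operations:
        for exp in expectation.changes:
            if (op.kind == exp.change_term
                    and classify_entity(op) == exp.applies_to
                    and classify_target(op, dialect) >= exp.affects):
                out[op.op_id] = {
                    "has_intention": sorted(expectation.intention),
                    "has_reason": sorted(expectation.reason),
                }
    return out


def check_expectation(delta: Delta, annotations: list[ChangeAnnotation],
                      expectation: Expectation) -> list[str]:
    """Return a list of ground-truth violations (empty when all satisfied)."""
    problems: list[str] = []
    for exp in expectation.changes:
        hit = any(
            ann.change_term == exp.change_term
            and ann.applies_to == exp.applies_to
            and ann.affects >= exp.affects
            and ann.order_only == exp.order_only
            for ann in annotations)
        if not hit:
            problems.append(f"no annotation matches expected change {exp}")
    ops = {op.op_id: op for op in delta.operations}
    for trig in expectation.triggers:
        matching = [op for op in delta.operations
                    if op.address.tags[-1] == trig.triggered_tag
                    and op.entity_kind == trig.triggered_entity]
        if not matching:
            problems.append(f"no operation matches trigger pattern {trig}")
            continue
        for op in matching:
            ok = any(ops[t].address.tags[-1] == trig.trigger_tag
                     for t in op.triggered_by if t in ops)
            if not ok:
                problems.append(
                    f"{op.op_id} ({trig.triggered_tag}) lacks a trigger on "
                    f"a {trig.trigger_tag} node")
    return problems
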