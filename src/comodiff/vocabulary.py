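"""The COMODI change vocabulary: term hierarchy, object properties, subsumption.

COMODI (COmputational MOdels DIffer) organises change concepts into four
branches around the central concept ``Change``:

* ``XmlEntity`` — what kind of XML entity was touched (node, attribute, text);
* ``Intention`` — what the change was meant to achieve (e.g. a correction);
* ``Reason`` — what made the change necessary (e.g. a typo, a mismatch with
  the publication, a changed format specification);
* ``Target`` — which layer of the model document is affected.  Five layers
  are distinguished: the format encoding (``ModelEncoding``), the semantic
  annotations (``ModelAnnotation``), the biological system
  (``ModelDefinition``), the simulation setup (``ModelSetup``) and the
  dynamics (``ModelBehaviour``).

A change individual is linked to these branches through exactly five object
properties: ``affects`` (→ Target), ``appliesTo`` (→ XmlEntity),
``hasIntention`` (→ Intention), ``hasReason`` (→ Reason) and
``wasTriggeredBy`` (→ another Change).

The built-in vocabulary is the core subset of the published ontology that
this package classifies against; the full released ontology (OWL or Turtle)
can be loaded with :func:`load_vocabulary_file`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .errors import UnknownTermError

DEFAULT_BASE_IRI = "http://purl.uni-rostock.de/comodi/comodi#"

ROOT_TERMS = ("Change", "XmlEntity", "Intention", "Reason", "Target")

_CURIE_LOCAL = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")


@dataclass(frozen=True)
class Term:
    """One vocabulary class: an id, a label, its parent term and a definition."""

    id: str
    label: str = ""
    parent: Optional[str] = None
    definition: str = ""

    def __post_init__(self):
        if not _CURIE_LOCAL.match(self.id):
            raise ValueError(f"term id {self.id!r} is not a valid CURIE local part")


@dataclass(frozen=True)
class ObjectProperty:
    """A typed relation from a Change individual to a term of another branch."""

    name: str
    domain: str
    range: str
    description: str = ""


#: (id, parent, label, definition) rows of the built-in core vocabulary.
_BUILTIN_TERMS = (
    ("Change", None, "change",
     "A single difference between two versions of a model document."),
    ("Insertion", "Change", "insertion", "An entity was added to the document."),
    ("Deletion", "Change", "deletion", "An entity was removed from the document."),
    ("Update", "Change", "update", "An entity's value was modified."),
    ("Move", "Change", "move", "An entity changed its position in the document."),
    ("XmlEntity", None, "XML entity", "A kind of entity in an XML document."),
    ("XmlNode", "XmlEntity", "XML node", "An XML element node."),
    ("XmlAttribute", "XmlEntity", "XML attribute", "An attribute of an XML element."),
    ("XmlText", "XmlEntity", "XML text", "Text content of an XML element."),
    ("Intention", None, "intention",
     "The aim of a change, particularly with respect to future consequences."),
    ("Correction", "Intention", "correction", "The change fixes an error."),
    ("Reason", None, "reason", "The cause that made a change necessary."),
    ("MismatchWithPublication", "Reason", "mismatch with publication",
     "The encoded model disagreed with the associated publication."),
    ("Typo", "Reason", "typo", "A typographical error in the document."),
    ("ChangedSpecification", "Reason", "changed specification",
     "The format specification the document adheres to was updated."),
    ("Target", None, "target", "The layer of the model document that a change affects."),
    ("ModelEncoding", "Target", "model encoding",
     "The formal encoding of the model document, e.g. the SBML level/version."),
    ("EntityName", "ModelEncoding", "entity name",
     "A human-readable name of an encoded entity."),
    ("EntityIdentifier", "ModelEncoding", "entity identifier",
     "A machine-readable identifier of an encoded entity."),
    ("ModelAnnotation", "Target", "model annotation",
     "The semantic annotation layer of the model document."),
    ("ModelDefinition", "Target", "model definition",
     "The definition of the modelled biological system."),
    ("ReactionNetworkDefinition", "ModelDefinition", "reaction network definition",
     "The structure of the encoded reaction network: species, reactions, stoichiometry."),
    ("FunctionDefinition", "ModelDefinition", "function definition",
     "A reusable mathematical function defined in the model."),
    ("KineticsDefinition", "ModelDefinition", "kinetics definition",
     "The rate law of a process, e.g. an SBML kineticLaw."),
    ("ModelSetup", "Target", "model setup",
     "The simulation setup of the model, e.g. parameter values."),
    ("ParameterSetup", "ModelSetup", "parameter setup",
     "The value or definition of a model parameter."),
    ("ModelBehaviour", "Target", "model behaviour",
     "The dynamic behaviour of the system; detailed terms are cross-referenced "
     "from the TEDDY ontology."),
)

_BUILTIN_PROPERTIES = (
    ObjectProperty("affects", "Change", "Target",
                   "Provides information about the parts in a model that were "
                   "affected by a change."),
    ObjectProperty("appliesTo", "Change", "XmlEntity",
                   "Stores information about the entity type in an XML document "
                   "that was changed."),
    ObjectProperty("hasIntention", "Change", "Intention",
                   "Links a change to an intention that was to be achieved by "
                   "the corresponding change."),
    ObjectProperty("hasReason", "Change", "Reason",
                   "Links a change to a reason that made this change necessary."),
    ObjectProperty("wasTriggeredBy", "Change", "Change",
                   "Represents dependencies among changes: a change might "
                   "trigger further changes."),
)


@dataclass
class Vocabulary:
    """A term hierarchy plus the five object properties.

    Terms form a forest of single-parent trees whose roots are the five
    root concepts; subsumption (:meth:`is_a`) is the reflexive-transitive
    closure of the parent relation.
    """

    terms: dict[str, Term] = field(default_factory=dict)
    properties: list[ObjectProperty] = field(default_factory=list)
    version: str = ""
    base_iri: str = DEFAULT_BASE_IRI

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def term(self, term_id: str) -> Term:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def add_term(self, term: Term) -> None:
        if term.id in self.terms:
            raise ValueError(f"duplicate term id {term.id!r}")
        self.terms[term.id] = term

    def ancestors(self, term_id: str) -> list[str]:
        """Parent chain of ``term_id``, starting at the term itself."""
        chain = [term_id]
        cur = self.term(term_id)
        seen = {term_id}
        while cur.parent is not None:
            if cur.parent in seen:
                raise ValueError(f"cycle in parent chain at {cur.parent!r}")
            chain.append(cur.parent)
            seen.add(cur.parent)
            cur = self.term(cur.parent)
        return chain

    def root_of(self, term_id: str) -> str:
        return self.ancestors(term_id)[-1]

    def is_a(self, term_id: str, ancestor_id: str) -> bool:
        """Reflexive subsumption: is ``term_id`` equal to or below ``ancestor_id``?"""
        self.term(ancestor_id)  # raise on unknown ancestor
        return ancestor_id in self.ancestors(term_id)

    def children(self, term_id: str) -> list[str]:
        self.term(term_id)
        return [t.id for t in self.terms.values() if t.parent == term_id]

    def iri(self, term_id: str) -> str:
        return self.base_iri + term_id

    def property(self, name: str) -> ObjectProperty:
        for p in self.properties:
            if p.name == name:
                return p
        raise KeyError(name)

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        for t in self.terms.values():
            if t.parent is not None and t.parent not in self.terms:
                raise ValueError(f"term {t.id!r} has unknown parent {t.parent!r}")
            root = self.root_of(t.id)  # also detects cycles
            if self.term(root).parent is not None:  # pragma: no cover - unreachable
                raise ValueError(f"parent chain of {t.id!r} does not end at a root")

    def _key(self):
        return (frozenset(self.terms.values()), frozenset(self.properties))

    def __eq__(self, other):
        if not isinstance(other, Vocabulary):
            return NotImplemented
        return self._key() == other._key()


def load_builtin_vocabulary() -> Vocabulary:
    """Return the built-in core COMODI vocabulary (idempotent)."""
    voc = Vocabulary(version="core-0.1", base_iri=DEFAULT_BASE_IRI)
    for tid, parent, label, definition in _BUILTIN_TERMS:
        voc.add_term(Term(tid, label=label, parent=parent, definition=definition))
    voc.properties = list(_BUILTIN_PROPERTIES)
    voc.validate()
    return voc


def is_a(voc: Vocabulary, term_id: str, ancestor_id: str) -> bool:
    """Module-level convenience wrapper for :meth:`Vocabulary.is_a`."""
    return voc.is_a(term_id, ancestor_id)


def _ontology_iri(base_iri: str) -> URIRef:
    return URIRef(base_iri.rstrip("#/"))


def to_graph(voc: Vocabulary) -> Graph:
    """Render a vocabulary as an rdflib graph (OWL classes + object properties)."""
    g = Graph()
    ns = Namespace(voc.base_iri)
    g.bind("comodi", ns)
    g.bind("owl", OWL)
    onto = _ontology_iri(voc.base_iri)
    g.add((onto, RDF.type, OWL.Ontology))
    if voc.version:
        g.add((onto, OWL.versionInfo, Literal(voc.version)))
    for t in voc.terms.values():
        s = ns[t.id]
        g.add((s, RDF.type, OWL.Class))
        if t.label:
            g.add((s, RDFS.label, Literal(t.label)))
        if t.definition:
            g.add((s, RDFS.comment, Literal(t.definition)))
        if t.parent is not None:
            g.add((s, RDFS.subClassOf, ns[t.parent]))
    for p in voc.properties:
        s = ns[p.name]
        g.add((s, RDF.type, OWL.ObjectProperty))
        g.add((s, RDFS.domain, ns[p.domain]))
        g.add((s, RDFS.range, ns[p.range]))
        if p.description:
            g.add((s, RDFS.comment, Literal(p.description)))
    return g


def export_turtle(voc: Vocabulary) -> str:
    """Serialize the vocabulary as Turtle; inverse of :func:`parse_turtle`."""
    return to_graph(voc).serialize(format="turtle")


def from_graph(g: Graph, base_iri: str = DEFAULT_BASE_IRI) -> Vocabulary:
    def local(uri: URIRef) -> str:
        s = str(uri)
        if s.startswith(base_iri):
            return s[len(base_iri):]
        return s.rsplit("#", 1)[-1].rsplit("/", 1)[-1]

    voc = Vocabulary(base_iri=base_iri)
    onto = _ontology_iri(base_iri)
    version = g.value(onto, OWL.versionInfo)
    voc.version = str(version) if version is not None else ""
    for s in sorted(g.subjects(RDF.type, OWL.Class)):
        if not isinstance(s, URIRef):
            continue
        parent = g.value(s, RDFS.subClassOf)
        label = g.value(s, RDFS.label)
        comment = g.value(s, RDFS.comment)
        voc.add_term(Term(
            local(s),
            label=str(label) if label else "",
            parent=local(parent) if isinstance(parent, URIRef) else None,
            definition=str(comment) if comment else "",
        ))
    for s in sorted(g.subjects(RDF.type, OWL.ObjectProperty)):
        if not isinstance(s, URIRef):
            continue
        dom = g.value(s, RDFS.domain)
        rng = g.value(s, RDFS.range)
        comment = g.value(s, RDFS.comment)
        voc.properties.append(ObjectProperty(
            local(s),
            domain=local(dom) if isinstance(dom, URIRef) else "",
            range=local(rng) if isinstance(rng, URIRef) else "",
            description=str(comment) if comment else "",
        ))
    return voc


def parse_turtle(text: str, base_iri: str = DEFAULT_BASE_IRI) -> Vocabulary:
    g = Graph()
    g.parse(data=text, format="turtle")
    return from_graph(g, base_iri=base_iri)


def load_vocabulary_file(path: str, base_iri: str = DEFAULT_BASE_IRI) -> Vocabulary:
    """Load a vocabulary from a Turtle or OWL (RDF/XML) file.

    The RDF format is guessed from the file extension (.ttl → Turtle,
    anything else → RDF/XML, the serialization the published ontology uses).
    """
    g = Graph()
    fmt = "turtle" if str(path).endswith((".ttl", ".turtle")) else "xml"
    g.parse(path, format=fmt)
    return from_graph(g, base_iri=base_iri)
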