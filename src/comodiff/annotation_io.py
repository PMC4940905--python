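"""RDF/Turtle serialization of change annotations.

Annotations are stored in a file of their own, separate from the diff XML,
so the diff stays small and the annotation layer can evolve independently.
Each change is identified by a fragment IRI on the diff-file reference
(``delta.xml#op7``); its triples are its Change subtype (``rdf:type``) and
the five COMODI object properties.  No blank nodes are emitted.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional, Sequence

from rdflib import Graph, Namespace, URIRef
from rdflib.namespace import RDF

from .classifier import ChangeAnnotation
from .errors import RangeViolationError, UnknownTermError
from .vocabulary import DEFAULT_BASE_IRI, Vocabulary, load_builtin_vocabulary

_PROPERTY_RANGES = {
    "appliesTo": "XmlEntity",
    "affects": "Target",
    "hasIntention": "Intention",
    "hasReason": "Reason",
}


def _validate(annotations: Sequence[ChangeAnnotation], voc: Vocabulary) -> None:
    for ann in annotations:
        if not voc.is_a(ann.change_term, "Change"):
            raise RangeViolationError("rdf:type", ann.change_term, "Change")
        if not voc.is_a(ann.applies_to, "XmlEntity"):
            raise RangeViolationError("appliesTo", ann.applies_to, "XmlEntity")
        for prop, terms in (("affects", ann.affects),
                            ("hasIntention", ann.has_intention),
                            ("hasReason", ann.has_reason)):
            for t in terms:
                if not voc.is_a(t, _PROPERTY_RANGES[prop]):
                    raise RangeViolationError(prop, t, _PROPERTY_RANGES[prop])


def write_turtle(annotations: Sequence[ChangeAnnotation],
                 delta_ref: str = "delta.xml",
                 base_iri: str = DEFAULT_BASE_IRI,
                 vocabulary: Optional[Vocabulary] = None) -> str:
    """Serialize annotations as Turtle; validates term ranges first."""
    voc = vocabulary if vocabulary is not None else load_builtin_vocabulary()
    _validate(annotations, voc)
    g = Graph()
    ns = Namespace(base_iri)
    g.bind("comodi", ns)
    for ann in annotations:
        s = URIRef(f"{delta_ref}#{ann.op_id}")
        g.add((s, RDF.type, ns[ann.change_term]))
        g.add((s, ns["appliesTo"], ns[ann.applies_to]))
        for t in sorted(ann.affects):
            g.add((s, ns["affects"], ns[t]))
        for t in sorted(ann.has_intention):
            g.add((s, ns["hasIntention"], ns[t]))
        for t in sorted(ann.has_reason):
            g.add((s, ns["hasReason"], ns[t]))
        for t in sorted(ann.was_triggered_by):
            g.add((s, ns["wasTriggeredBy"], URIRef(f"{delta_ref}#{t}")))
    return g.serialize(format="turtle")


def _fragment(uri: URIRef) -> str:
    return str(uri).rsplit("#", 1)[-1]


def read_turtle(text: str, vocabulary: Optional[Vocabulary] = None,
                base_iri: str = DEFAULT_BASE_IRI,
                ) -> tuple[list[ChangeAnnotation], list[str]]:
    """Parse a Turtle annotation file back into ChangeAnnotations.

    Returns ``(annotations, warnings)``.  Unknown predicates or vocabulary
    terms are reported in the warning list, never silently dropped: unknown
    terms stay attached to their annotation as opaque ids.
    """
    voc = vocabulary if vocabulary is not None else load_builtin_vocabulary()
    g = Graph()
    if text.strip():
        g.parse(data=text, format="turtle")
    ns = Namespace(base_iri)
    warnings: list[str] = []

    per_subject: dict[str, dict] = {}

    def record(subject) -> dict:
        op_id = _fragment(subject)
        return per_subject.setdefault(op_id, {
            "change_term": None, "applies_to": None, "affects": set(),
            "has_intention": set(), "has_reason": set(), "was_triggered_by": set(),
        })

    def term_of(obj, prop: str) -> str:
        t = str(obj)
        if t.startswith(base_iri):
            t = t[len(base_iri):]
        if t not in voc:
            warnings.append(f"unknown term {t!r} as object of {prop}")
        return t

    for s, p, o in g:
        rec = record(s)
        if p == RDF.type:
            rec["change_term"] = term_of(o, "rdf:type")
        elif p == ns["appliesTo"]:
            rec["applies_to"] = term_of(o, "appliesTo")
        elif p == ns["affects"]:
            rec["affects"].add(term_of(o, "affects"))
        elif p == ns["hasIntention"]:
            rec["has_intention"].add(term_of(o, "hasIntention"))
        elif p == ns["hasReason"]:
            rec["has_reason"].add(term_of(o, "hasReason"))
        elif p == ns["wasTriggeredBy"]:
            rec["was_triggered_by"].add(_fragment(o))
        else:
            warnings.append(f"unknown predicate {p}")

    def sort_key(op_id: str):
        m = re.match(r"^op(\d+)$", op_id)
        return (0, int(m.group(1))) if m else (1, op_id)

    annotations = []
    for op_id in sorted(per_subject, key=sort_key):
        rec = per_subject[op_id]
        annotations.append(ChangeAnnotation(
            op_id=op_id,
            change_term=rec["change_term"] or "",
            applies_to=rec["applies_to"] or "",
            affects=frozenset(rec["affects"]),
            has_intention=frozenset(rec["has_intention"]),
            has_reason=frozenset(rec["has_reason"]),
            was_triggered_by=frozenset(rec["was_triggered_by"]),
        ))
    return annotations, warnings
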