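"""Automatic COMODI annotation of change operations.

Two branches of the vocabulary can be assigned mechanically from a delta:
the *XmlEntity* of an operation (node, attribute or text — read off the
address) and the *Target* layer (read off the dialect's rule table, which
maps document locations like a parameter's ``value`` attribute or a
``kineticLaw`` subtree to Target terms).  Intention and Reason describe why
a human made a change and are therefore never inferred; they are accepted
from user-supplied annotations only, as is ModelBehaviour (judging an
effect on the dynamics would require simulating the model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx

from ._dialects import get_dialect
from .errors import RangeViolationError
from .filters import is_order_only
from .vocabulary import Vocabulary, load_builtin_vocabulary
from .xml_diff import ChangeOperation, Delta, infer_structural_triggers


@dataclass(frozen=True)
class ChangeAnnotation:
    """COMODI terms attached to one change operation."""

    op_id: str
    change_term: str
    applies_to: str
    affects: frozenset[str] = frozenset()
    has_intention: frozenset[str] = frozenset()
    has_reason: frozenset[str] = frozenset()
    was_triggered_by: frozenset[str] = frozenset()
    order_only: bool = False

    def terms(self) -> frozenset[str]:
        """All vocabulary terms carried by this annotation."""
        return (frozenset({self.change_term, self.applies_to})
                | self.affects | self.has_intention | self.has_reason)

    def key(self):
        """RDF-carried content (everything except the order_only flag)."""
        return (self.op_id, self.change_term, self.applies_to, self.affects,
                self.has_intention, self.has_reason, self.was_triggered_by)


def classify_entity(op: ChangeOperation) -> str:
    """XmlAttribute for attribute operations, XmlText for text, else XmlNode."""
    addr = op.address
    if addr.attribute is not None:
        return "XmlAttribute"
    if addr.text:
        return "XmlText"
    return "XmlNode"


def _local_attr(name: Optional[str]) -> Optional[str]:
    if name is None:
        return None
    if name.startswith("{"):
        return name.rsplit("}", 1)[-1]
    return name  # includes xmlns / xmlns:prefix pseudo-attributes


def classify_target(op: ChangeOperation, dialect: str) -> frozenset[str]:
    """Target terms for an operation, from the dialect's rule table.

    Only the most specific terms are stored; ancestors (e.g. ModelSetup
    above ParameterSetup) are implied via subsumption at query time.
    Unmatched locations yield the empty set.
    """
    dl = get_dialect(dialect)
    addr = op.address
    attr = addr.attribute
    if attr is not None and not (attr == "xmlns" or attr.startswith("xmlns:")):
        attr = _local_attr(attr)
    return dl.classify_path(addr.tags, attr)


def infer_triggers(delta: Delta) -> Delta:
    """Populate wasTriggeredBy links between causally dependent operations.

    A node deletion triggers the deletions of its attributes, text and
    child nodes (so deleting an SBML reaction triggers the deletion of its
    kineticLaw subtree); insertions behave symmetrically.  Links point from
    the triggered operation to its trigger.  Idempotent.
    """
    infer_structural_triggers(delta)
    g = nx.DiGraph()
    g.add_nodes_from(op.op_id for op in delta.operations)
    for op in delta.operations:
        for t in op.triggered_by:
            g.add_edge(op.op_id, t)
    if not nx.is_directed_acyclic_graph(g):  # pragma: no cover - defensive
        raise RuntimeError("internal error: trigger graph contains a cycle")
    return delta


def _as_frozenset(value) -> frozenset[str]:
    if value is None:
        return frozenset()
    if isinstance(value, str):
        return frozenset({value})
    return frozenset(value)


_USER_KEYS = {
    "has_intention": "has_intention", "hasIntention": "has_intention",
    "intention": "has_intention",
    "has_reason": "has_reason", "hasReason": "has_reason", "reason": "has_reason",
    "affects": "affects",
}


def _normalize_user_entry(entry: Mapping) -> dict[str, frozenset[str]]:
    out = {"has_intention": frozenset(), "has_reason": frozenset(),
           "affects": frozenset()}
    for k, v in entry.items():
        if k in _USER_KEYS:
            out[_USER_KEYS[k]] = out[_USER_KEYS[k]] | _as_frozenset(v)
    return out


def _check_range(voc: Vocabulary, prop: str, terms: Iterable[str], root: str) -> None:
    for t in terms:
        if not voc.is_a(t, root):  # raises UnknownTermError for unknown ids
            raise RangeViolationError(prop, t, root)


def annotate_delta(delta: Delta, dialect: Optional[str] = None,
                   user_annotations: Optional[Mapping[str, Mapping]] = None,
                   vocabulary: Optional[Vocabulary] = None) -> list[ChangeAnnotation]:
    """One :class:`ChangeAnnotation` per operation in the delta.

    The change term, XmlEntity, Target terms and trigger links are derived
    automatically; intentions, reasons and extra user-asserted Target terms
    (e.g. ModelBehaviour) come from ``user_annotations``, a map from op_id
    to ``{hasIntention: [...], hasReason: [...], affects: [...]}``.  Terms
    are validated against the object-property ranges before anything is
    returned.
    """
    dialect = dialect or delta.dialect
    voc = vocabulary if vocabulary is not None else load_builtin_vocabulary()
    infer_triggers(delta)
    user = {k: _normalize_user_entry(v) for k, v in (user_annotations or {}).items()}
    annotations = []
    for op in delta.operations:
        extra = user.get(op.op_id, None)
        intention = extra["has_intention"] if extra else frozenset()
        reason = extra["has_reason"] if extra else frozenset()
        user_affects = extra["affects"] if extra else frozenset()
        _check_range(voc, "hasIntention", intention, "Intention")
        _check_range(voc, "hasReason", reason, "Reason")
        _check_range(voc, "affects", user_affects, "Target")
        annotations.append(ChangeAnnotation(
            op_id=op.op_id,
            change_term=op.kind,
            applies_to=classify_entity(op),
            affects=classify_target(op, dialect) | user_affects,
            has_intention=intention,
            has_reason=reason,
            was_triggered_by=frozenset(op.triggered_by),
            order_only=is_order_only(op, dialect),
        ))
    return annotations
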