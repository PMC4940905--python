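"""Tree matching and delta computation for XML-encoded model documents.

A *delta* is the ordered set of edit operations — insertions, deletions,
updates and moves of XML entities (nodes, attributes, text) — that
transforms one version of a document into another.  The module's defining
contract is the patch round trip: for any two documents A and B,
``patch(A, compute_delta(A, B))`` is canonically equal to B.

Matching is id-anchored and greedy rather than an optimal tree-edit-distance
solver: SBML and CellML entities carry stable identifiers (``id``,
``metaid``, ``name``, ``cmeta:id``), so anchoring on those and falling back
to positional matching under matched parents is both fast and gives the
entity-level operations the annotation layer needs.

Namespace declarations are treated as pseudo-attributes (``xmlns``,
``xmlns:prefix``) of the element that declares them; this is what makes a
format-specification switch (e.g. an SBML level upgrade, which changes the
document's default namespace) visible as an ordinary attribute update.
"""

from __future__ import annotations

import copy
import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

from lxml import etree

from ._dialects import get_dialect
from .errors import (
    DeltaSchemaError,
    InconsistentMappingError,
    MalformedDocumentError,
    PatchConflictError,
    UnresolvableAddressError,
)

DocumentLike = Union[str, bytes, etree._Element, etree._ElementTree]

KINDS = ("Insertion", "Deletion", "Update", "Move")
ENTITY_KINDS = ("XmlNode", "XmlAttribute", "XmlText")

_PARSER = etree.XMLParser(remove_comments=True, remove_pis=True)

_STEP_RE = re.compile(r"^([^\[\]/]+)\[([0-9]+)\]$")


# ---------------------------------------------------------------------------
# parsing and low-level helpers

def parse_document(doc: DocumentLike) -> etree._Element:
    """Return the root element of ``doc`` (XML text, bytes, element or tree)."""
    if isinstance(doc, etree._ElementTree):
        return doc.getroot()
    if isinstance(doc, etree._Element):
        return doc
    data = doc.encode() if isinstance(doc, str) else doc
    try:
        return etree.fromstring(data, _PARSER)
    except etree.XMLSyntaxError as exc:
        raise MalformedDocumentError(str(exc)) from exc


def load_document(path: str) -> etree._Element:
    try:
        return etree.parse(str(path), _PARSER).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise MalformedDocumentError(f"{path}: {exc}") from exc


def local_name(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def namespace_of(tag: str) -> Optional[str]:
    if tag.startswith("{"):
        return tag[1:].split("}", 1)[0]
    return None


def _iter_elements(root: etree._Element) -> Iterator[etree._Element]:
    for el in root.iter():
        if isinstance(el.tag, str):
            yield el


def _element_children(el: etree._Element) -> list[etree._Element]:
    return [c for c in el if isinstance(c.tag, str)]


def element_text(el: etree._Element) -> str:
    """Whitespace-normalized direct text content of an element.

    Runs of whitespace collapse to one space and leading/trailing whitespace
    is trimmed, so serialization-tool churn (pretty-printing) does not
    produce spurious text updates.  Text before and between children is
    merged into a single value.
    """
    parts = []
    if el.text:
        parts.append(el.text)
    for c in el:
        if c.tail:
            parts.append(c.tail)
    return " ".join(" ".join(parts).split())


def _set_element_text(el: etree._Element, value: str) -> None:
    el.text = value or None
    for c in el:
        c.tail = None


def declared_namespaces(el: etree._Element) -> dict[str, str]:
    """Namespace declarations introduced *at* this element, as pseudo-attributes."""
    parent = el.getparent()
    pmap = dict(parent.nsmap) if parent is not None else {}
    out = {}
    for prefix, uri in el.nsmap.items():
        if pmap.get(prefix) != uri:
            out["xmlns" if prefix is None else f"xmlns:{prefix}"] = uri
    return out


def all_attributes(el: etree._Element) -> dict[str, str]:
    """Real attributes (Clark-named when namespaced) plus namespace pseudo-attributes."""
    out = {str(k): str(v) for k, v in el.attrib.items()}
    out.update(declared_namespaces(el))
    return out


def _is_ns_decl(name: str) -> bool:
    return name == "xmlns" or name.startswith("xmlns:")


def path_of(el: etree._Element) -> str:
    """1-based tag-indexed path of an element, e.g. ``sbml[1]/model[1]/listOfSpecies[1]/species[2]``."""
    steps = []
    node = el
    while True:
        parent = node.getparent()
        tag = local_name(node.tag)
        if parent is None:
            steps.append(f"{tag}[1]")
            break
        same = [c for c in _element_children(parent) if local_name(c.tag) == tag]
        steps.append(f"{tag}[{same.index(node) + 1}]")
        node = parent
    return "/".join(reversed(steps))


def _parse_path(path: str) -> list[tuple[str, int]]:
    steps = []
    for raw in path.split("/"):
        m = _STEP_RE.match(raw)
        if m is None:
            raise DeltaSchemaError(f"malformed address step {raw!r} in path {path!r}")
        steps.append((m.group(1), int(m.group(2))))
    return steps


# ---------------------------------------------------------------------------
# addresses and operations

@dataclass(frozen=True)
class XmlAddress:
    """Address of one XML entity: an element path plus an optional attribute
    name or text flag (mutually exclusive)."""

    path: str
    attribute: Optional[str] = None
    text: bool = False

    def __post_init__(self):
        if self.attribute is not None and self.text:
            raise ValueError("attribute and text addressing are mutually exclusive")

    def __str__(self) -> str:
        if self.attribute is not None:
            return f"{self.path}/@{self.attribute}"
        if self.text:
            return f"{self.path}/#text"
        return self.path

    @classmethod
    def parse(cls, s: str) -> "XmlAddress":
        if s.endswith("/#text"):
            return cls(s[: -len("/#text")], text=True)
        if "/@" in s:
            path, attr = s.rsplit("/@", 1)
            return cls(path, attribute=attr)
        return cls(s)

    @property
    def tags(self) -> tuple[str, ...]:
        return tuple(tag for tag, _ in _parse_path(self.path))

    @property
    def parent_path(self) -> Optional[str]:
        return self.path.rsplit("/", 1)[0] if "/" in self.path else None


@dataclass
class ChangeOperation:
    """One edit on an addressed XML entity.

    For node insertions/deletions, ``new_value``/``old_value`` carry the
    element's qualified (Clark) tag so that patching can recreate the node
    in the right namespace.
    """

    op_id: str
    kind: str
    entity_kind: str
    address_a: Optional[XmlAddress] = None
    address_b: Optional[XmlAddress] = None
    old_value: Optional[str] = None
    new_value: Optional[str] = None
    triggered_by: set[str] = field(default_factory=set)

    @property
    def address(self) -> XmlAddress:
        addr = self.address_a if self.address_a is not None else self.address_b
        assert addr is not None
        return addr

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        bad = []
        if self.kind not in KINDS:
            bad.append(f"{self.op_id}: unknown kind {self.kind!r}")
        if self.entity_kind not in ENTITY_KINDS:
            bad.append(f"{self.op_id}: unknown entity kind {self.entity_kind!r}")
        if self.kind == "Insertion":
            if self.address_a is not None or self.old_value is not None:
                bad.append(f"{self.op_id}: Insertion must not carry address_a/old_value")
            if self.address_b is None:
                bad.append(f"{self.op_id}: Insertion requires address_b")
        elif self.kind == "Deletion":
            if self.address_b is not None or self.new_value is not None:
                bad.append(f"{self.op_id}: Deletion must not carry address_b/new_value")
            if self.address_a is None:
                bad.append(f"{self.op_id}: Deletion requires address_a")
        elif self.kind == "Update":
            if self.address_a is None:
                bad.append(f"{self.op_id}: Update requires address_a")
            if self.old_value is None or self.new_value is None:
                bad.append(f"{self.op_id}: Update requires old and new values")
            elif self.old_value == self.new_value:
                bad.append(f"{self.op_id}: Update with identical values")
        elif self.kind == "Move":
            if self.address_a is None or self.address_b is None:
                bad.append(f"{self.op_id}: Move requires both addresses")
        return bad


@dataclass
class Delta:
    """An ordered set of change operations transforming document A into B."""

    operations: list[ChangeOperation] = field(default_factory=list)
    doc_a_ref: str = "A"
    doc_b_ref: str = "B"
    dialect: str = "generic-xml"

    def __iter__(self) -> Iterator[ChangeOperation]:
        return iter(self.operations)

    def __len__(self) -> int:
        return len(self.operations)

    @property
    def is_empty(self) -> bool:
        return not self.operations

    def op(self, op_id: str) -> ChangeOperation:
        for o in self.operations:
            if o.op_id == op_id:
                return o
        raise KeyError(op_id)


# ---------------------------------------------------------------------------
# matching

class Mapping:
    """A partial one-to-one mapping between element nodes of two documents."""

    def __init__(self, root_a: etree._Element, root_b: etree._Element):
        self.root_a = root_a
        self.root_b = root_b
        self._a2b: dict[etree._Element, etree._Element] = {}
        self._b2a: dict[etree._Element, etree._Element] = {}

    def add(self, a: etree._Element, b: etree._Element) -> None:
        if a in self._a2b or b in self._b2a:
            raise InconsistentMappingError("node mapped twice")
        self._a2b[a] = b
        self._b2a[b] = a

    def get_b(self, a: etree._Element) -> Optional[etree._Element]:
        return self._a2b.get(a)

    def get_a(self, b: etree._Element) -> Optional[etree._Element]:
        return self._b2a.get(b)

    def has_a(self, a) -> bool:
        return a in self._a2b

    def has_b(self, b) -> bool:
        return b in self._b2a

    def pairs(self) -> list[tuple[etree._Element, etree._Element]]:
        return list(self._a2b.items())

    def __len__(self) -> int:
        return len(self._a2b)

    def check_consistent(self) -> None:
        if len(self._a2b) != len(self._b2a):
            raise InconsistentMappingError("mapping is not one-to-one")
        for a, b in self._a2b.items():
            if self._b2a.get(b) is not a:
                raise InconsistentMappingError("mapping is not one-to-one")


def match_trees(doc_a: DocumentLike, doc_b: DocumentLike,
                dialect: str = "generic-xml") -> Mapping:
    """Match nodes of two documents.

    Priority: (1) equal value of a dialect identity attribute on same-tag
    elements (unique on both sides); (2) equal tag + equal name attribute;
    (3) positional among unmatched same-tag siblings under matched parents.
    """
    dl = get_dialect(dialect)
    root_a = parse_document(doc_a)
    root_b = parse_document(doc_b)
    mapping = Mapping(root_a, root_b)

    def match_by_attr(attr: str) -> None:
        def index(root, has):
            idx: dict[tuple[str, str], list] = {}
            for el in _iter_elements(root):
                if has(el):
                    continue
                v = el.get(attr)
                if v is not None:
                    idx.setdefault((local_name(el.tag), v), []).append(el)
            return idx

        ia = index(root_a, mapping.has_a)
        ib = index(root_b, mapping.has_b)
        for key, els in ia.items():
            partners = ib.get(key, [])
            if len(els) == 1 and len(partners) == 1:
                mapping.add(els[0], partners[0])

    for attr in dl.identity_attributes:
        match_by_attr(attr)
    for attr in dl.name_attributes:
        if attr not in dl.identity_attributes:
            match_by_attr(attr)

    # positional matching under matched parents, starting at the roots
    if (not mapping.has_a(root_a) and not mapping.has_b(root_b)
            and local_name(root_a.tag) == local_name(root_b.tag)):
        mapping.add(root_a, root_b)

    order = {el: i for i, el in enumerate(_iter_elements(root_a))}
    queue = sorted(mapping.pairs(), key=lambda ab: order[ab[0]])
    qi = 0
    while qi < len(queue):
        a, b = queue[qi]
        qi += 1
        free_a: dict[str, list] = {}
        free_b: dict[str, list] = {}
        for c in _element_children(a):
            if not mapping.has_a(c):
                free_a.setdefault(local_name(c.tag), []).append(c)
        for c in _element_children(b):
            if not mapping.has_b(c):
                free_b.setdefault(local_name(c.tag), []).append(c)
        for tag, cas in free_a.items():
            for ca, cb in zip(cas, free_b.get(tag, [])):
                mapping.add(ca, cb)
                queue.append((ca, cb))
    return mapping


# ---------------------------------------------------------------------------
# delta computation

def _lis_keep_indices(seq: list[int]) -> set[int]:
    """Indices of one longest strictly increasing subsequence (deterministic)."""
    n = len(seq)
    if n == 0:
        return set()
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if seq[j] < seq[i] and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: (best[i], -i))
    keep: set[int] = set()
    while end != -1:
        keep.add(end)
        end = prev[end]
    return keep


def infer_structural_triggers(delta: Delta) -> Delta:
    """Populate wasTriggeredBy links from address containment (in place).

    The deletion of a node triggers the deletion of its attributes, its text
    and its child nodes; insertions behave symmetrically.  The result is a
    forest, hence acyclic.
    """
    node_ops: dict[tuple[str, str], str] = {}
    for op in delta.operations:
        if op.entity_kind == "XmlNode" and op.kind in ("Insertion", "Deletion"):
            side = "a" if op.kind == "Deletion" else "b"
            node_ops[(side, op.address.path)] = op.op_id
    for op in delta.operations:
        if op.kind == "Deletion":
            side, addr = "a", op.address_a
        elif op.kind == "Insertion":
            side, addr = "b", op.address_b
        else:
            op.triggered_by = set()
            continue
        if op.entity_kind == "XmlNode":
            parent = addr.parent_path
            key = (side, parent) if parent else None
        else:
            key = (side, addr.path)
        trigger = node_ops.get(key) if key else None
        op.triggered_by = {trigger} if trigger and trigger != op.op_id else set()
    return delta


def compute_delta(doc_a: DocumentLike = None, doc_b: DocumentLike = None,
                  mapping: Optional[Mapping] = None,
                  dialect: str = "generic-xml",
                  doc_a_ref: str = "A", doc_b_ref: str = "B") -> Delta:
    """Compute the delta between two documents.

    Unmatched A nodes yield deletions, unmatched B nodes insertions (one
    operation per node, attribute and non-empty text value), matched nodes
    with differing attributes/text yield per-entity updates, and matched
    nodes that changed parent or sibling order yield moves.
    """
    get_dialect(dialect)
    if mapping is None:
        mapping = match_trees(doc_a, doc_b, dialect)
    else:
        mapping.check_consistent()
    root_a, root_b = mapping.root_a, mapping.root_b

    ops: list[ChangeOperation] = []
    counter = itertools.count(1)

    def emit(**kw) -> ChangeOperation:
        op = ChangeOperation(op_id=f"op{next(counter)}", **kw)
        ops.append(op)
        return op

    a_elements = list(_iter_elements(root_a))
    b_elements = list(_iter_elements(root_b))
    b_pos = {el: i for i, el in enumerate(b_elements)}

    def emit_subtree_entity_ops(el, kind, make_address, value_field):
        path = path_of(el)
        node_op = emit(kind=kind, entity_kind="XmlNode",
                       **make_address(XmlAddress(path)),
                       **{value_field: el.tag})
        for name, value in sorted(all_attributes(el).items()):
            emit(kind=kind, entity_kind="XmlAttribute",
                 **make_address(XmlAddress(path, attribute=name)),
                 **{value_field: value})
        txt = element_text(el)
        if txt:
            emit(kind=kind, entity_kind="XmlText",
                 **make_address(XmlAddress(path, text=True)),
                 **{value_field: txt})
        return node_op

    # --- deletions: unmatched nodes of A, document order
    for el in a_elements:
        if mapping.has_a(el):
            continue
        emit_subtree_entity_ops(el, "Deletion",
                                lambda addr: {"address_a": addr}, "old_value")

    # --- updates: attribute/text differences on matched pairs
    for el in a_elements:
        b = mapping.get_b(el)
        if b is None:
            continue
        pa, pb = path_of(el), path_of(b)
        aat, bat = all_attributes(el), all_attributes(b)
        # A changed element namespace (e.g. an SBML level upgrade) is one
        # semantic event, reported as an "xmlns" update at the top of the
        # renamespaced subtree, however the documents spell the declarations.
        nsa, nsb = namespace_of(el.tag), namespace_of(b.tag)
        if nsa != nsb:
            ap, bp = el.getparent(), b.getparent()
            inherited = (ap is not None and bp is not None
                         and mapping.get_b(ap) is bp
                         and namespace_of(ap.tag) == nsa
                         and namespace_of(bp.tag) == nsb)
            if not inherited:
                if nsa is None:
                    emit(kind="Insertion", entity_kind="XmlAttribute",
                         address_b=XmlAddress(pb, attribute="xmlns"), new_value=nsb)
                elif nsb is None:
                    emit(kind="Deletion", entity_kind="XmlAttribute",
                         address_a=XmlAddress(pa, attribute="xmlns"), old_value=nsa)
                else:
                    emit(kind="Update", entity_kind="XmlAttribute",
                         address_a=XmlAddress(pa, attribute="xmlns"),
                         address_b=XmlAddress(pb, attribute="xmlns"),
                         old_value=nsa, new_value=nsb)
            aat = {k: v for k, v in aat.items()
                   if not (_is_ns_decl(k) and v in (nsa, nsb))}
            bat = {k: v for k, v in bat.items()
                   if not (_is_ns_decl(k) and v in (nsa, nsb))}
        for name in sorted(set(aat) | set(bat)):
            va, vb = aat.get(name), bat.get(name)
            if va == vb:
                continue
            if vb is None:
                emit(kind="Deletion", entity_kind="XmlAttribute",
                     address_a=XmlAddress(pa, attribute=name), old_value=va)
            elif va is None:
                emit(kind="Insertion", entity_kind="XmlAttribute",
                     address_b=XmlAddress(pb, attribute=name), new_value=vb)
            else:
                emit(kind="Update", entity_kind="XmlAttribute",
                     address_a=XmlAddress(pa, attribute=name),
                     address_b=XmlAddress(pb, attribute=name),
                     old_value=va, new_value=vb)
        ta, tb = element_text(el), element_text(b)
        if ta != tb:
            if not tb:
                emit(kind="Deletion", entity_kind="XmlText",
                     address_a=XmlAddress(pa, text=True), old_value=ta)
            elif not ta:
                emit(kind="Insertion", entity_kind="XmlText",
                     address_b=XmlAddress(pb, text=True), new_value=tb)
            else:
                emit(kind="Update", entity_kind="XmlText",
                     address_a=XmlAddress(pa, text=True),
                     address_b=XmlAddress(pb, text=True),
                     old_value=ta, new_value=tb)

    # --- moves and insertions, interleaved in B document order so that
    # patching can place each node once its earlier siblings are in place
    placements: list[tuple[int, str, object]] = []
    same_parent: dict[tuple, list[tuple]] = {}
    for el in a_elements:
        b = mapping.get_b(el)
        if b is None:
            continue
        ap, bp = el.getparent(), b.getparent()
        if ap is None or bp is None:
            continue
        if mapping.get_b(ap) is not bp:
            placements.append((b_pos[b], "move", (el, b)))
        else:
            same_parent.setdefault((ap, bp), []).append((el, b))
    for (ap, bp), prs in same_parent.items():
        child_pos = {c: i for i, c in enumerate(_element_children(bp))}
        seq = [child_pos[b] for _, b in prs]
        keep = _lis_keep_indices(seq)
        for i, (a, b) in enumerate(prs):
            if i not in keep:
                placements.append((b_pos[b], "move", (a, b)))
    for el in b_elements:
        if not mapping.has_b(el):
            placements.append((b_pos[el], "insert", el))
    placements.sort(key=lambda t: t[0])
    for _, what, payload in placements:
        if what == "move":
            a, b = payload
            emit(kind="Move", entity_kind="XmlNode",
                 address_a=XmlAddress(path_of(a)), address_b=XmlAddress(path_of(b)))
        else:
            emit_subtree_entity_ops(payload, "Insertion",
                                    lambda addr: {"address_b": addr}, "new_value")

    delta = Delta(ops, doc_a_ref=doc_a_ref, doc_b_ref=doc_b_ref, dialect=dialect)
    return infer_structural_triggers(delta)


def diff(doc_a: DocumentLike, doc_b: DocumentLike,
         dialect: str = "generic-xml", doc_a_ref: str = "A",
         doc_b_ref: str = "B") -> Delta:
    """Match two documents and compute their delta in one call."""
    mapping = match_trees(doc_a, doc_b, dialect)
    return compute_delta(mapping=mapping, dialect=dialect,
                         doc_a_ref=doc_a_ref, doc_b_ref=doc_b_ref)


# ---------------------------------------------------------------------------
# patching

def _renamespace(el: etree._Element, old_uri: Optional[str], new_uri: str) -> None:
    for n in el.iter():
        if not isinstance(n.tag, str):
            continue
        if namespace_of(n.tag) == old_uri:
            n.tag = f"{{{new_uri}}}{local_name(n.tag)}" if new_uri else local_name(n.tag)


def patch(doc_a: DocumentLike, delta: Delta) -> etree._Element:
    """Apply a delta to document A; the result is canonically equal to B.

    Operations are applied deletions-first, then updates, then node
    placements (moves and node insertions in their recorded order), then
    attribute/text insertions.
    """
    problems = [p for op in delta.operations for p in op.validate()]
    if problems:
        raise DeltaSchemaError("; ".join(problems))

    root = copy.deepcopy(parse_document(doc_a))
    wrapper = etree.Element("__document__")
    wrapper.append(root)

    def resolve(path: str, op: ChangeOperation) -> etree._Element:
        cur = wrapper
        for tag, idx in _parse_path(path):
            same = [c for c in _element_children(cur) if local_name(c.tag) == tag]
            if idx > len(same):
                raise UnresolvableAddressError(op.op_id, path)
            cur = same[idx - 1]
        return cur

    # Addresses into A are resolved up front, against the unmodified tree;
    # later structural edits then work on node identity, so deleting a
    # subtree does not invalidate the addresses of operations inside it.
    nodes_a: dict[str, etree._Element] = {}
    for op in delta.operations:
        if op.address_a is not None:
            nodes_a[op.op_id] = resolve(op.address_a.path, op)

    writes: set[tuple[str, str]] = set()

    def claim(path: str, slot: str, op: ChangeOperation) -> None:
        key = (path, slot)
        if key in writes:
            raise PatchConflictError(
                f"operation {op.op_id!r} writes already-written address {path!r}/{slot}")
        writes.add(key)

    # phase 1: deletions
    for op in delta.operations:
        if op.kind != "Deletion":
            continue
        el = nodes_a[op.op_id]
        if op.entity_kind == "XmlNode":
            parent = el.getparent()
            if parent is not None:
                parent.remove(el)
        elif op.entity_kind == "XmlAttribute":
            name = op.address_a.attribute
            if name == "xmlns":
                if namespace_of(el.tag) == op.old_value:
                    _renamespace(el, op.old_value, "")
                continue
            if _is_ns_decl(name):
                continue  # declarations are re-derived from use at serialization
            if el.get(name) is None:
                raise UnresolvableAddressError(op.op_id, str(op.address_a))
            del el.attrib[name]
        else:
            _set_element_text(el, "")

    # phase 2: updates
    for op in delta.operations:
        if op.kind != "Update":
            continue
        el = nodes_a[op.op_id]
        if op.entity_kind == "XmlAttribute":
            name = op.address_a.attribute
            claim(op.address_a.path, "@" + name, op)
            if _is_ns_decl(name):
                _renamespace(el, op.old_value, op.new_value)
            else:
                el.set(name, op.new_value)
        else:
            claim(op.address_a.path, "#text", op)
            _set_element_text(el, op.new_value)

    # phase 3: node placements — detach all moved nodes, then place moves
    # and freshly created nodes in the recorded (B document) order
    for op in delta.operations:
        if op.kind == "Move":
            el = nodes_a[op.op_id]
            parent = el.getparent()
            if parent is not None:
                parent.remove(el)
    for op in delta.operations:
        if not (op.kind == "Move"
                or (op.kind == "Insertion" and op.entity_kind == "XmlNode")):
            continue
        steps = _parse_path(op.address_b.path)
        parent_el = wrapper
        for tag, idx in steps[:-1]:
            same = [c for c in _element_children(parent_el) if local_name(c.tag) == tag]
            if idx > len(same):
                raise UnresolvableAddressError(op.op_id, op.address_b.path)
            parent_el = same[idx - 1]
        tag, idx = steps[-1]
        if op.kind == "Move":
            el = nodes_a[op.op_id]
        else:
            el = etree.Element(op.new_value or tag)
        same = [c for c in _element_children(parent_el) if local_name(c.tag) == tag]
        if idx - 1 < len(same):
            parent_el.insert(parent_el.index(same[idx - 1]), el)
        elif same:
            parent_el.insert(parent_el.index(same[-1]) + 1, el)
        else:
            parent_el.append(el)

    # phase 4: attribute and text insertions (the tree is now node-complete,
    # so B-side addresses resolve)
    for op in delta.operations:
        if op.kind != "Insertion" or op.entity_kind == "XmlNode":
            continue
        el = resolve(op.address_b.path, op)
        if op.entity_kind == "XmlAttribute":
            name = op.address_b.attribute
            if name == "xmlns":
                _renamespace(el, namespace_of(el.tag), op.new_value)
            elif _is_ns_decl(name):
                pass  # prefixed declarations follow from attribute/tag use
            else:
                claim(op.address_b.path, "@" + name, op)
                el.set(name, op.new_value)
        else:
            claim(op.address_b.path, "#text", op)
            _set_element_text(el, op.new_value)

    children = _element_children(wrapper)
    if len(children) != 1:
        raise PatchConflictError(
            f"patched document has {len(children)} root elements")
    result = children[0]
    wrapper.remove(result)
    return result


# ---------------------------------------------------------------------------
# canonicalization

def canonicalize(doc: DocumentLike) -> str:
    """Deterministic serialization defining document equality.

    Attributes are emitted in sorted order, text is whitespace-normalized
    and merged per element, namespace prefixes are renamed ``n0, n1, ...``
    in sorted-URI order, and unused namespace declarations are dropped.
    """
    root = parse_document(doc)
    uris: set[str] = set()
    for el in _iter_elements(root):
        u = namespace_of(el.tag)
        if u:
            uris.add(u)
        for k in el.attrib:
            ku = namespace_of(str(k))
            if ku:
                uris.add(ku)
    nsmap = {f"n{i}": u for i, u in enumerate(sorted(uris))} or None

    def build(src: etree._Element, dst: etree._Element) -> None:
        for k in sorted(str(k) for k in src.attrib):
            dst.set(k, src.attrib[k])
        t = element_text(src)
        if t:
            dst.text = t
        for c in _element_children(src):
            build(c, etree.SubElement(dst, c.tag))

    new_root = etree.Element(root.tag, nsmap=nsmap)
    build(root, new_root)
    return etree.tostring(new_root, encoding="unicode")


def documents_equal(doc_a: DocumentLike, doc_b: DocumentLike) -> bool:
    return canonicalize(doc_a) == canonicalize(doc_b)


# ---------------------------------------------------------------------------
# delta (de)serialization

def _op_sort_key(op_id: str):
    m = re.match(r"^op(\d+)$", op_id)
    return (0, int(m.group(1))) if m else (1, op_id)


def serialize_delta(delta: Delta) -> str:
    """Serialize a delta as diff XML (one ``operation`` element per edit)."""
    root = etree.Element("modelDelta")
    root.set("docA", delta.doc_a_ref)
    root.set("docB", delta.doc_b_ref)
    root.set("dialect", delta.dialect)
    for op in delta.operations:
        e = etree.SubElement(root, "operation")
        e.set("id", op.op_id)
        e.set("kind", op.kind)
        e.set("entity", op.entity_kind)
        if op.address_a is not None:
            e.set("addressA", str(op.address_a))
        if op.address_b is not None:
            e.set("addressB", str(op.address_b))
        if op.old_value is not None:
            e.set("oldValue", op.old_value)
        if op.new_value is not None:
            e.set("newValue", op.new_value)
        if op.triggered_by:
            e.set("triggeredBy", " ".join(sorted(op.triggered_by, key=_op_sort_key)))
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def parse_delta(text: Union[str, bytes]) -> Delta:
    root = parse_document(text)
    if local_name(root.tag) != "modelDelta":
        raise DeltaSchemaError(f"unexpected root element {root.tag!r}")
    delta = Delta(doc_a_ref=root.get("docA", "A"), doc_b_ref=root.get("docB", "B"),
                  dialect=root.get("dialect", "generic-xml"))
    problems: list[str] = []
    for e in _element_children(root):
        if local_name(e.tag) != "operation":
            problems.append(f"unexpected element {e.tag!r}")
            continue
        op = ChangeOperation(
            op_id=e.get("id", ""),
            kind=e.get("kind", ""),
            entity_kind=e.get("entity", ""),
            address_a=XmlAddress.parse(e.get("addressA")) if e.get("addressA") else None,
            address_b=XmlAddress.parse(e.get("addressB")) if e.get("addressB") else None,
            old_value=e.get("oldValue"),
            new_value=e.get("newValue"),
            triggered_by=set((e.get("triggeredBy") or "").split()),
        )
        problems.extend(op.validate())
        delta.operations.append(op)
    ids = [op.op_id for op in delta.operations]
    if len(set(ids)) != len(ids):
        problems.append("duplicate operation ids")
    known = set(ids)
    for op in delta.operations:
        for t in op.triggered_by:
            if t not in known:
                problems.append(f"{op.op_id}: unknown trigger {t!r}")
    if problems:
        raise DeltaSchemaError("; ".join(problems))
    return delta
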