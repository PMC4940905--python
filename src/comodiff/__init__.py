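"""comodiff: semantic diffing of XML-encoded computational biology models.

Computes the delta (insertions, deletions, updates, moves) between two
versions of an SBML or CellML document, annotates every change with terms
from the COMODI change ontology, links causally dependent changes, and
filters change sets by ontology term with subsumption.
"""

from __future__ import annotations

from typing import Mapping, Optional

from .annotation_io import read_turtle, write_turtle
from .classifier import (
    ChangeAnnotation,
    annotate_delta,
    classify_entity,
    classify_target,
    infer_triggers,
)
from .errors import ComodiffError
from .filters import PROFILES, FilterProfile, collapse_versions, filter_changes, is_order_only
from .fixtures import MutationSpec, apply_mutation, make_base_model, make_version_pair
from .vocabulary import (
    Term,
    Vocabulary,
    export_turtle,
    is_a,
    load_builtin_vocabulary,
    load_vocabulary_file,
    parse_turtle,
)
from .xml_diff import (
    ChangeOperation,
    Delta,
    Mapping as NodeMapping,
    XmlAddress,
    canonicalize,
    compute_delta,
    diff,
    documents_equal,
    match_trees,
    parse_delta,
    patch,
    serialize_delta,
)

__version__ = "0.1.0"


def annotate_documents(doc_a, doc_b, dialect: str = "generic-xml",
                       user_annotations: Optional[Mapping] = None,
                       ) -> tuple[Delta, list[ChangeAnnotation]]:
    """Diff two documents and annotate every change in one call."""
    delta = diff(doc_a, doc_b, dialect=dialect)
    annotations = annotate_delta(delta, dialect=dialect,
                                 user_annotations=user_annotations)
    return delta, annotations


__all__ = [
    "ChangeAnnotation", "ChangeOperation", "ComodiffError", "Delta",
    "FilterProfile", "MutationSpec", "NodeMapping", "PROFILES", "Term",
    "Vocabulary", "XmlAddress", "annotate_delta", "annotate_documents",
    "apply_mutation", "canonicalize", "classify_entity", "classify_target",
    "collapse_versions", "compute_delta", "diff", "documents_equal",
    "export_turtle", "filter_changes", "infer_triggers", "is_a",
    "is_order_only", "load_builtin_vocabulary", "load_vocabulary_file",
    "make_base_model", "make_version_pair", "match_trees", "parse_delta",
    "parse_turtle", "patch", "read_turtle", "serialize_delta", "write_turtle",
]
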