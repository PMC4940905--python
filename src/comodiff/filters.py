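"""Filtering annotated change sets by COMODI terms with subsumption.

Which changes matter depends on the audience: a curator cares about
annotation-scheme updates that a modeller can ignore, and nobody cares
about reorderings inside containers whose element order carries no meaning
(e.g. the SBML listOfParameters).  A :class:`FilterProfile` captures one
such point of view; two common ones ship as named profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

from ._dialects import Dialect, get_dialect
from .vocabulary import Vocabulary, load_builtin_vocabulary
from .xml_diff import ChangeOperation, local_name, _parse_path

if TYPE_CHECKING:  # pragma: no cover
    from .classifier import ChangeAnnotation


@dataclass(frozen=True)
class FilterProfile:
    """Which changes to keep: include/exclude term sets plus flags.

    A change is kept iff (the include set is empty, or at least one of its
    terms is subsumed by an include term) and none of its terms is subsumed
    by an exclude term.  With ``use_subsumption=False`` only exact term
    matches count.
    """

    include_terms: frozenset[str] = frozenset()
    exclude_terms: frozenset[str] = frozenset()
    drop_order_only: bool = False
    use_subsumption: bool = True

    def __post_init__(self):
        overlap = self.include_terms & self.exclude_terms
        if overlap:
            raise ValueError(f"include and exclude sets overlap: {sorted(overlap)}")


#: Named audience profiles.  The "modeller" profile hides pure annotation
#: churn and order-only shuffles; the "curator" profile keeps everything
#: except order-only shuffles.
PROFILES: dict[str, FilterProfile] = {
    "modeller": FilterProfile(exclude_terms=frozenset({"ModelAnnotation"}),
                              drop_order_only=True),
    "curator": FilterProfile(drop_order_only=True),
}


def _container_of(path: str) -> Optional[str]:
    steps = _parse_path(path)
    if len(steps) < 2:
        return None
    return steps[-2][0]


def is_order_only(op: ChangeOperation, dialect: str | Dialect) -> bool:
    """True iff the operation is a within-parent move inside a container
    whose element order carries no meaning for the encoded system."""
    if op.kind != "Move" or op.address_a is None or op.address_b is None:
        return False
    if op.address_a.parent_path != op.address_b.parent_path:
        return False
    dl = get_dialect(dialect) if isinstance(dialect, str) else dialect
    container = _container_of(op.address_a.path)
    return container is not None and container in dl.unordered_containers


def _matches_any(voc: Vocabulary, term: str, bag: frozenset[str],
                 use_subsumption: bool) -> bool:
    if term not in voc:
        # terms outside the vocabulary (e.g. opaque cross-references) only
        # match exactly
        return term in bag
    if use_subsumption:
        return any(voc.is_a(term, t) for t in bag)
    return term in bag


def filter_changes(annotations: Sequence["ChangeAnnotation"],
                   profile: FilterProfile,
                   vocabulary: Optional[Vocabulary] = None) -> list["ChangeAnnotation"]:
    """Return the subset of ``annotations`` the profile keeps.

    Idempotent and monotone: enlarging the include set never shrinks the
    output, enlarging the exclude set never grows it.
    """
    voc = vocabulary if vocabulary is not None else load_builtin_vocabulary()
    for t in profile.include_terms | profile.exclude_terms:
        voc.term(t)  # raises UnknownTermError for bad profile terms
    kept = []
    for ann in annotations:
        if profile.drop_order_only and ann.order_only:
            continue
        terms = ann.terms()
        if profile.include_terms and not any(
                _matches_any(voc, t, profile.include_terms, profile.use_subsumption)
                for t in terms):
            continue
        if profile.exclude_terms and any(
                _matches_any(voc, t, profile.exclude_terms, profile.use_subsumption)
                for t in terms):
            continue
        kept.append(ann)
    return kept


def collapse_versions(version_series: Sequence[Sequence["ChangeAnnotation"]],
                      profile: FilterProfile,
                      vocabulary: Optional[Vocabulary] = None) -> list[int]:
    """Indices (0-based) of versions whose delta retains at least one change
    after filtering; runs of filtered-empty versions collapse away."""
    voc = vocabulary if vocabulary is not None else load_builtin_vocabulary()
    return [i for i, anns in enumerate(version_series)
            if filter_changes(anns, profile, voc)]
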