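# Methods

`comodiff` computes and semantically annotates the differences between two
versions of an XML-encoded computational biology model (SBML Level 2/3
core, CellML core, or arbitrary XML). This note documents the model of a
"change" the package implements, the algorithmic choices behind the
differ, the classification rules, what the synthetic fixtures do and do
not emulate, and known limitations.

## The change model

A **delta** is an ordered set of operations — `Insertion`, `Deletion`,
`Update`, `Move` — on addressed XML entities (element nodes, attributes,
text), sufficient to transform document A into document B. The defining
contract is the patch round trip:

    patch(A, compute_delta(A, B))  ≡  B   (under canonicalization)

Every operation is annotated with terms from the COMODI change vocabulary.
Two branches are assigned automatically:

* **appliesTo** (`XmlEntity`): node / attribute / text, read off the
  operation's address;
* **affects** (`Target`): which layer of the model document is touched —
  the format encoding (`ModelEncoding`), the semantic annotations
  (`ModelAnnotation`), the biological system (`ModelDefinition` and its
  children), the simulation setup (`ModelSetup`/`ParameterSetup`), or the
  dynamics (`ModelBehaviour`).

**hasIntention** and **hasReason** describe *why* a human changed the
model; they cannot be derived from the XML and are accepted only from
user-supplied annotation maps. `ModelBehaviour` is likewise never
auto-assigned — judging an effect on the dynamics would require simulating
the model — and is accepted from user annotations only.

Dependent changes are linked with **wasTriggeredBy**: deleting a node
triggers the deletions of its attributes, its text and its child nodes
(so deleting a reaction triggers the deletion of its kinetic law);
insertions behave symmetrically. The trigger graph is a forest by
construction, hence acyclic; `infer_triggers` re-derives the links purely
from operation addresses and is idempotent.

Only the most specific Target terms are stored. Ancestors are implied at
query time through subsumption: a `ParameterSetup` change *is* a
`ModelSetup` change when you ask. Subsumption is a reflexive partial
order over a single-parent hierarchy (a tree per branch root); nothing in
the vocabulary needs multiple inheritance, and single parents keep
subsumption a simple chain walk.

## Matching and delta computation

The differ is an **id-anchored greedy matcher**, not an optimal
tree-edit-distance solver. SBML and CellML entities carry stable
identifiers, so optimality buys nothing for the annotation use case.
Matching priority:

1. equal value of a dialect identity attribute on same-local-tag elements
   (SBML: `id`, then `metaid`; CellML: `name`, then `cmeta:id`), applied
   only where the value is unique on both sides;
2. equal tag + equal `name` attribute;
3. positional: i-th unmatched same-tag child under matched parents,
   breadth-first from the matched roots.

Unmatched A nodes become deletions, unmatched B nodes insertions (one
operation per node, per attribute, per non-empty text value — the
sub-entity operations carry triggers to their node operation). Matched
nodes are compared attribute-by-attribute and on whitespace-normalized
text.

**Moves.** A matched node whose parents' matches differ is a cross-parent
move. Within one matched parent pair, the moved children are those outside
the longest increasing subsequence of the children's positions in B: this
reports every real reorder while not flagging siblings merely shifted by
an insertion or deletion. Move operations carry no sub-operations (the
subtree travels with the node).

**Namespaces.** Declarations are treated as pseudo-attributes
(`xmlns`, `xmlns:prefix`) of the declaring element, which makes a
format-specification switch (an SBML level upgrade changes the default
namespace URI) visible as one ordinary attribute update classified as
`ModelEncoding`. Because serializers spell the same URI with different
prefixes, the differ compares the *effective* namespace of matched
elements and emits a single `xmlns` update at the top of a renamespaced
subtree; prefix-only declaration changes are no-ops under canonical
equality.

**Patching** applies deletions first, then updates, then node placements
(moves and node insertions, in the recorded B-document order), then
attribute/text insertions. Addresses into A are resolved against the
unmodified tree up front, so operations inside a deleted subtree stay
resolvable; placement in B-document order guarantees that when a node is
inserted at same-tag index *k*, its earlier same-tag siblings are already
in place. Unresolvable addresses raise an error naming the operation;
double writes to one address raise a conflict error.

**Canonicalization** defines document equality: attributes sorted by
name, text whitespace-collapsed and merged per element, namespace
prefixes renamed `n0, n1, …` in sorted-URI order, unused declarations
dropped, comments and processing instructions ignored. Canonicalization
is idempotent.

## Addressing and serialization

Entities are addressed by 1-based tag-indexed paths
(`sbml[1]/model[1]/listOfParameters[1]/parameter[2]`, plus `/@attr` or
`/#text`), local names only. Deltas serialize to a small diff-XML dialect
(`modelDelta`/`operation` elements carrying kind, entity kind, addresses,
`oldValue`/`newValue`, `triggeredBy`); serialization is deterministic and
`parse ∘ serialize` is the identity.

Annotations serialize to Turtle, **stored separately from the diff file**:
each change is the fragment IRI `<delta-ref>#<op id>`, typed with its
Change subtype and linked through the five object properties (`affects`,
`appliesTo`, `hasIntention`, `hasReason`, `wasTriggeredBy`). No blank
nodes are emitted, so round trips are exact at the triple level. Deleting
the annotation file never invalidates the diff and vice versa. The
`order_only` convenience flag on in-memory annotations is not an RDF
statement and does not round-trip through Turtle.

## Classification rules

Target rules are data, not code: `data/rules.yaml` maps path patterns
(`**` = any run of steps) and attribute names to Target term sets; all
matching rules are unioned, so a species `name` update yields
`{EntityName, ReactionNetworkDefinition}`. Notable choices:

* MathML inside `kineticLaw` → `KineticsDefinition`; inside
  `functionDefinition` → `FunctionDefinition` (nearest enclosing
  construct).
* `name` attributes → `EntityName`; `id`/`metaid` → `EntityIdentifier`
  (placed under `ModelEncoding`, the XML-encoding subtree of Target).
* Root `level`/`version` attributes and any namespace pseudo-attribute →
  `ModelEncoding`.
* CellML core has no explicit reaction list, so component/connection
  structure maps to the generic `ModelDefinition`, not
  `ReactionNetworkDefinition`; a variable's `initial_value` plays the
  parameter-value role.

`ChangedSpecification` lives under `Reason` (it states *why* a version
exists — the format specification changed); the corresponding automatic
Target term for such changes is `ModelEncoding`.

## Filtering

A `FilterProfile` keeps a change iff (the include set is empty, or at
least one of the change's terms is subsumed by an include term) and none
of its terms is subsumed by an exclude term; exclusion beats inclusion.
Filtering is idempotent and monotone in both term sets.

Order-only changes — moves within one parent inside a container declared
unordered by the dialect — can be dropped wholesale. The unordered
container list is dialect configuration; for SBML it covers the
`listOf*` containers whose order carries no meaning, while `listOfRules`
and `listOfEvents` are conservatively treated as ordered. Two audience
profiles ship built in: `modeller` (drop annotation-layer and order-only
changes) and `curator` (drop order-only changes only).
`collapse_versions` reduces a version series to the 0-based indices of
versions that retain at least one change after filtering.

## Synthetic fixtures

`fixtures.make_base_model(dialect, n_species, n_reactions, seed)` builds a
deterministic SBML L2V4 (or CellML 1.0) document with species,
parameters (a Km/Vmax pair per reaction), reactions with Michaelis–Menten
kinetic laws in MathML, and an RDF annotation block. Defaults (4 species,
2 reactions) keep each document at the scale of a small curated kinetic
model while exercising every construct the classifier has rules for.

Eight scripted mutations emulate the recurring change classes seen in
model repositories — `parameter_value_update`, `typo_rename`
(Gulcose → Glucose), `species_insert`, `species_delete`,
`reaction_delete`, `spec_upgrade` (L2V4 → L3V1 namespace + level/version),
`annotation_edit`, `reshuffle_parameters` — each returning the mutated
document plus ground truth: the expected (change kind, XmlEntity, Target)
triples, trigger patterns, order-only flags and the intention/reason a
curator would record. The test suite runs every mutation across five
seeds (40 version pairs) through the full pipeline and checks the patch
round trip and that computed annotations contain the ground truth.

What the fixtures do **not** emulate: real repository deltas mix many
simultaneous edits by different tools, use SBML extension packages,
contain units/compartment subtleties and large MathML, and include
whole-file rewrites by round-tripping editors. Passing fixtures therefore
demonstrate the operation-level contracts (round trip, classification,
triggers, filtering), not recall on arbitrary historical model pairs.

## Known limitations

* Insertion addresses carry only same-tag sibling indices; an element
  inserted among heterogeneous siblings with no same-tag neighbour is
  appended at its parent's end, which can mis-order a patched document in
  that (fixture-free) corner case.
* The diff-XML dialect is this package's own; it is compatible in spirit,
  not bit-compatible, with other delta formats.
* The matcher is greedy; pathological documents (many identical unnamed
  siblings with edits) can yield non-minimal but still correct deltas.
* The built-in vocabulary is the core subset needed for automatic
  annotation (27 terms); the full released ontology can be loaded from a
  Turtle/OWL file with `load_vocabulary_file` and used everywhere a
  vocabulary is accepted.
* No OWL-DL reasoning or consistency checking; subsumption is the only
  inference, and provenance (who/with which tool) is out of scope.
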