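# comodiff

Semantic diffing of XML-encoded computational biology models.

Models in open repositories (BioModels, the Physiome Model Repository)
evolve: parameter values are corrected, typos fixed, species and reactions
added or removed, documents upgraded to new format specifications,
annotation schemes changed. A plain XML diff shows *that* something
changed; it does not say *what kind* of change it was, whether it can
affect simulation results, or whether it is tool churn that can be
ignored. `comodiff` closes that gap for SBML (Level 2/3 core) and CellML
(core) documents — and any other XML — by

1. computing a **delta**: the insertions, deletions, updates and moves of
   XML entities (nodes, attributes, text) that transform version A into
   version B, with the contract `patch(A, delta(A, B)) ≡ B` under
   canonicalization;
2. **annotating** every change with terms from the COMODI change ontology:
   the entity kind it applies to (`appliesTo` → XmlEntity), the model
   layer it affects (`affects` → Target: ModelEncoding, ModelAnnotation,
   ModelDefinition, ModelSetup, ModelBehaviour), and — supplied by the
   user, never guessed — the intention and reason behind it
   (`hasIntention`, `hasReason`);
3. linking causally dependent changes with `wasTriggeredBy` (deleting a
   reaction triggers the deletion of its kinetic law);
4. **filtering** annotated change sets by ontology term with subsumption
   (asking for `ModelSetup` changes also returns `ParameterSetup`
   changes), dropping order-only reshuffles, and collapsing version series
   to the versions that contain relevant changes.

Deltas serialize to a small diff-XML dialect; annotations serialize to
RDF/Turtle in a separate file that references changes as fragment IRIs
(`delta.xml#op1`).

## Worked example

The classic case: a parameter value is corrected because the encoded model
disagreed with the publication. Version A contains
`<parameter id="Km1" value="23.24" units="molesperlitre"/>`; in version B
the value reads `23.42`.

```python
import comodiff as cd

A = '''<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="m">
    <listOfParameters>
      <parameter id="Km1" value="23.24" units="molesperlitre"/>
    </listOfParameters>
  </model>
</sbml>'''
B = A.replace("23.24", "23.42")

delta = cd.diff(A, B, dialect="sbml")
print(cd.serialize_delta(delta))
```

```xml
<modelDelta docA="A" docB="B" dialect="sbml">
  <operation id="op1" kind="Update" entity="XmlAttribute"
             addressA="sbml[1]/model[1]/listOfParameters[1]/parameter[1]/@value"
             addressB="sbml[1]/model[1]/listOfParameters[1]/parameter[1]/@value"
             oldValue="23.24" newValue="23.42"/>
</modelDelta>
```

One operation: an update of an XML attribute, carrying the old and the new
value. Annotating it (the intention/reason are the curator's statement;
the rest is automatic):

```python
user = {"op1": {"hasIntention": ["Correction"],
                "hasReason": ["MismatchWithPublication"]}}
anns = cd.annotate_delta(delta, "sbml", user_annotations=user)
print(cd.write_turtle(anns, delta_ref="delta.xml"))
```

```turtle
@prefix comodi: <http://purl.uni-rostock.de/comodi/comodi#> .

<delta.xml#op1> a comodi:Update ;
    comodi:affects comodi:ParameterSetup ;
    comodi:appliesTo comodi:XmlAttribute ;
    comodi:hasIntention comodi:Correction ;
    comodi:hasReason comodi:MismatchWithPublication .
```

The change is recognised as a `ParameterSetup` change — and because
`ParameterSetup` is-a `ModelSetup`, a filter asking for simulation-setup
changes keeps it:

```python
from comodiff import FilterProfile, filter_changes
kept = filter_changes(anns, FilterProfile(include_terms=frozenset({"ModelSetup"})))
assert [a.op_id for a in kept] == ["op1"]
```

## Command line

```
comodi diff a.xml b.xml --dialect sbml -o delta.xml    # exit 0/1/2: same/differ/error
comodi annotate delta.xml --user-annotations notes.yaml -o changes.ttl
comodi filter changes.ttl --include ChangedSpecification
comodi vocab export -o comodi-core.ttl
comodi fixtures --mutation typo_rename --seed 1 -o fixture_dir/
```

`comodi fixtures` generates synthetic model version pairs by scripted
mutations (parameter updates, typo renames, species/reaction edits,
specification upgrades, annotation edits, parameter reshuffles) with known
ground-truth annotations — the same generator the test suite uses.

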