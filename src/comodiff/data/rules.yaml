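# Dialect configuration: identity attributes used for tree matching,
# containers whose child order carries no meaning, and the rule table that
# maps changed document locations to COMODI Target terms.
#
# Rule semantics: a rule matches an operation if its `path` pattern matches
# the operation's element path (local names, no indices; `*` matches one
# step, `**` any run of steps) and, when an `attributes` list is present,
# the operation is an attribute operation whose local attribute name matches
# one of the listed names (fnmatch patterns allowed; namespace-qualified
# attributes are compared by local name, `xmlns`/`xmlns:*` address namespace
# declarations).  The Target sets of all matching rules are unioned.
dialects:
  sbml:
    identity_attributes: ["id", "metaid"]
    name_attributes: ["name"]
    unordered_containers:
      - listOfParameters
      - listOfSpecies
      - listOfReactions
      - listOfCompartments
      - listOfUnitDefinitions
      - listOfFunctionDefinitions
      - listOfSpeciesTypes
      - listOfCompartmentTypes
    target_rules:
      - {path: "**/parameter", targets: [ParameterSetup]}
      - {path: "**/kineticLaw", targets: [KineticsDefinition]}
      - {path: "**/kineticLaw/**", targets: [KineticsDefinition]}
      - {path: "**/functionDefinition", targets: [FunctionDefinition]}
      - {path: "**/functionDefinition/**", targets: [FunctionDefinition]}
      - {path: "**/species", targets: [ReactionNetworkDefinition]}
      - {path: "**/reaction", targets: [ReactionNetworkDefinition]}
      - {path: "**/listOfReactants/**", targets: [ReactionNetworkDefinition]}
      - {path: "**/listOfProducts/**", targets: [ReactionNetworkDefinition]}
      - {path: "**/listOfModifiers/**", targets: [ReactionNetworkDefinition]}
      - {path: "**/annotation", targets: [ModelAnnotation]}
      - {path: "**/annotation/**", targets: [ModelAnnotation]}
      - {path: "sbml", attributes: ["level", "version"], targets: [ModelEncoding]}
      - {path: "**", attributes: ["xmlns", "xmlns:*"], targets: [ModelEncoding]}
      - {path: "**", attributes: ["name"], targets: [EntityName]}
      - {path: "**", attributes: ["id", "metaid"], targets: [EntityIdentifier]}
  cellml:
    identity_attributes: ["name", "{http://www.cellml.org/metadata/1.0#}id"]
    name_attributes: []
    unordered_containers:
      - component
    target_rules:
      - {path: "**/variable", attributes: ["initial_value"], targets: [ParameterSetup]}
      - {path: "**/math", targets: [KineticsDefinition]}
      - {path: "**/math/**", targets: [KineticsDefinition]}
      - {path: "**/component", targets: [ModelDefinition]}
      - {path: "**/connection", targets: [ModelDefinition]}
      - {path: "**/connection/**", targets: [ModelDefinition]}
      - {path: "**/RDF", targets: [ModelAnnotation]}
      - {path: "**/RDF/**", targets: [ModelAnnotation]}
      - {path: "**", attributes: ["xmlns", "xmlns:*"], targets: [ModelEncoding]}
      - {path: "**", attributes: ["name"], targets: [EntityName]}
      - {path: "**", attributes: ["id"], targets: [EntityIdentifier]}
  generic-xml:
    identity_attributes: ["id"]
    name_attributes: ["name"]
    unordered_containers: []
    target_rules: []
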