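"""Exception hierarchy for comodiff."""


class ComodiffError(Exception):
    """Base class for all comodiff errors."""


class MalformedDocumentError(ComodiffError):
    """An input document is not well-formed XML; carries parser diagnostics."""


class UnknownTermError(ComodiffError):
    """A term id was looked up that does not exist in the vocabulary."""

    def __init__(self, term_id: str):
        self.term_id = term_id
        super().__init__(f"unknown vocabulary term: {term_id!r}")


class UnknownDialectError(ComodiffError):
    """A dialect name is not one of the configured dialects."""


class InconsistentMappingError(ComodiffError):
    """A node mapping violates the one-to-one constraint."""


class UnresolvableAddressError(ComodiffError):
    """A delta operation's address does not resolve in the target document."""

    def __init__(self, op_id: str, address: str):
        self.op_id = op_id
        self.address = address
        super().__init__(f"operation {op_id!r}: address {address!r} does not resolve")


class PatchConflictError(ComodiffError):
    """Two operations write to the same address."""


class DeltaSchemaError(ComodiffError):
    """A serialized delta violates the diff-XML schema; lists offending elements."""


class RangeViolationError(ComodiffError):
    """An annotation term violates the range of its object property."""

    def __init__(self, prop: str, term_id: str, expected_root: str):
        self.prop = prop
        self.term_id = term_id
        self.expected_root = expected_root
        super().__init__(
            f"term {term_id!r} is not in the range of {prop!r} (expected a term under {expected_root!r})"
        )


class InvalidCountError(ComodiffError):
    """Invalid entity counts requested from the model generator."""


class TargetMissingError(ComodiffError):
    """A scripted mutation's target entity does not exist in the document."""
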