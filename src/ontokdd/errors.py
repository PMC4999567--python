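"""Exception hierarchy shared across the package."""


class OntokddError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(OntokddError):
    """An ontology document does not parse or violates the document schema."""


class DanglingReferenceError(OntokddError):
    """A declared element refers to an undeclared entity, attribute or hierarchy."""


class UnknownConceptError(OntokddError, KeyError):
    """A concept id is not present in the hierarchy being queried."""


class ContractError(OntokddError):
    """An operation received input violating a documented precondition."""


class ConfigError(OntokddError):
    """Invalid run or generator configuration."""
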