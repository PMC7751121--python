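"""Exception hierarchy.

Model *validation* problems are reported as diagnostics, not exceptions;
exceptions signal inconsistencies between a model and the data it is applied
to, or misuse of the API.
"""


class PhenokitError(Exception):
    """Base class for all phenokit errors."""


class ModelError(PhenokitError):
    """Structural misuse of the model API (duplicate names, bad references)."""


class DataTypeMismatchError(PhenokitError):
    """A value's datatype is incompatible with a restriction or class."""


class UnitMismatchError(PhenokitError):
    """A data item's unit differs from the unit declared on its class."""


class MultipleItemsError(PhenokitError):
    """More than one item arrived for a class without an aggregate function."""


class ExpressionSyntaxError(PhenokitError):
    """Boolean expression or formula text could not be parsed."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message if position is None else f"{message} (at position {position})")
        self.position = position


class MissingAtomError(PhenokitError):
    """A Boolean expression references an atom absent from the membership map."""


class FormulaEvaluationError(PhenokitError):
    """Type error, missing required operand or arithmetic failure in a formula."""


class AggregateError(PhenokitError):
    """An aggregate function was applied to items it is not defined on."""


class DnfExplosionError(PhenokitError):
    """DNF conversion would exceed the configured conjunction budget."""


class FhirMappingError(PhenokitError):
    """A FHIR resource or query could not be produced or interpreted."""


class MetadataImportError(PhenokitError):
    """A dataset/metadata specification violates the import dialect."""
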