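"""Exception hierarchy for the edgotype pipeline."""


class EdgotypeError(Exception):
    """Base class for all package-specific errors."""


class InvalidScenarioError(EdgotypeError, ValueError):
    """A synthetic-data request is geometrically or statistically impossible."""


class ParseError(EdgotypeError, ValueError):
    """A tabular or structural input could not be parsed.

    Carries ``line`` (1-based) when the offending location is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptyStructureError(EdgotypeError, ValueError):
    """A coordinate file contained no usable ATOM records."""


class MissingChainError(EdgotypeError, KeyError):
    """A requested chain identifier is absent from the structure."""


class TableMissError(EdgotypeError, KeyError):
    """A residue type is absent from a lookup table."""


class DegenerateInputError(EdgotypeError, ValueError):
    """A statistical comparison received input with no usable variation."""


class SchemaError(EdgotypeError, ValueError):
    """A mutation table is missing a required column."""


class CoordinateError(EdgotypeError, ValueError):
    """A mutation position lies beyond the sequence it refers to."""


class IncompleteGeometryError(EdgotypeError, ValueError):
    """A mutation lacks the RSA needed to classify its location."""


class MissingDdgError(EdgotypeError, ValueError):
    """A mutation lacks the ddG record its location class requires."""


class DegenerateTableError(EdgotypeError, ValueError):
    """A contingency table has a zero margin."""


class EmptyClassError(EdgotypeError, ValueError):
    """A phenotype class has zero total count."""


class UndefinedPosteriorError(EdgotypeError, ZeroDivisionError):
    """The marginal edgotype probability is zero, so posteriors are undefined."""


class NoOverlapError(EdgotypeError, ValueError):
    """Predicted and experimental call sets share no mutation keys."""


class MissingInputError(EdgotypeError, FileNotFoundError):
    """A pipeline stage input file is absent."""
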