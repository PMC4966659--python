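"""Exception types shared across the package."""


class SnpConvergeError(Exception):
    """Base class for package errors."""


class SchemaError(SnpConvergeError):
    """An input table is missing a required column."""


class EmptyCatalogError(SnpConvergeError):
    """The disease-SNP catalogue contains no rows."""


class RowParseError(SnpConvergeError):
    """A row of an input table could not be parsed; carries the line number."""


class ConfigError(SnpConvergeError):
    """A run or generator configuration is invalid or infeasible."""


class UndefinedSimilarityError(SnpConvergeError):
    """A semantic similarity was requested for a term without information content."""


class DegreeConservationError(SnpConvergeError):
    """A permuted network failed the exact node-degree conservation check."""


class ConvergenceError(SnpConvergeError):
    """A model fit did not converge (e.g. perfect separation in logistic regression)."""
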