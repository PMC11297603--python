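"""Exception hierarchy. Everything raised on purpose derives from MTFNError."""


class MTFNError(Exception):
    """Base class for all package errors."""


class SchemaError(MTFNError):
    """An input table is missing a mapped column or is otherwise malformed."""


class ValidationError(MTFNError):
    """An argument violates an operation's contract."""


class FeaturizationError(MTFNError):
    """A structure string could not be converted to a fingerprint."""


class SplitError(MTFNError):
    """A task cannot be stratified-split (e.g. a class is absent)."""


class UndefinedAUCError(MTFNError):
    """AUC requested for a score vector whose labels contain one class only."""


class UndefinedCorrelationError(MTFNError):
    """Pearson correlation requested for a zero-variance vector."""


class GeneratorError(MTFNError):
    """A synthetic-data configuration is internally infeasible."""
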