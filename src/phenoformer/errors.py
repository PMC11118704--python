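"""Exception types shared across the package."""


class PhenoformerError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PhenoformerError, ValueError):
    """Input data violates a container invariant (negative values, NaN, ...)."""


class ParameterError(PhenoformerError, ValueError):
    """A parameter is outside its legal range."""


class SchemaError(PhenoformerError, ValueError):
    """A phenotype field or category is unknown to the declared schema."""


class SupportError(PhenoformerError, ValueError):
    """Not enough observations to run an analysis."""
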