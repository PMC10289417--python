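"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """A parameter is outside its documented domain."""


class InvalidDataError(ValueError):
    """Input data violates a structural requirement (missing values,
    non-binary occurrence cells, zero-norm trait vectors, ...)."""


class NumericalError(ArithmeticError):
    """A linear-algebra step failed beyond what regularization repairs."""
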