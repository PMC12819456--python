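"""Exception hierarchy used across the package."""


class CovertFnirsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CovertFnirsError, ValueError):
    """An argument or configuration field is invalid; the message names it."""


class ValidationError(CovertFnirsError, ValueError):
    """A data object violates one of its invariants."""


class FormatError(CovertFnirsError, ValueError):
    """A file does not conform to the expected on-disk format."""


class DesignError(CovertFnirsError, ValueError):
    """A GLM design matrix is unusable (e.g. rank deficient)."""


class ModelError(CovertFnirsError, ValueError):
    """A numerical model is degenerate (e.g. singular extinction matrix)."""
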