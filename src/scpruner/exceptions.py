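"""Exception hierarchy; the CLI maps each class to a fixed exit code."""


class ScprunerError(Exception):
    """Base class for all scpruner errors."""


class FormatError(ScprunerError):
    """A file could not be parsed in the declared format."""


class ValidationError(ScprunerError):
    """Input data violates a documented precondition."""


class DegenerateDataError(ScprunerError):
    """Data became unusable (empty matrix, single-class labels, too few cells)."""


class IncompatibleDataError(ScprunerError):
    """Reference and query cannot be brought onto a common gene space."""


class ConfigError(ScprunerError):
    """Invalid run configuration."""
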