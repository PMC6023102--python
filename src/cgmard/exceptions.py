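"""Exception hierarchy for cgmard."""


class CgmardError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CgmardError, ValueError):
    """An input violates a documented precondition."""


class EmptyResultError(CgmardError):
    """An operation produced no usable output (e.g. no pairable points)."""


class CoverageError(CgmardError):
    """Reference values fail the glycemic-range coverage rules for WMARD."""


class GeneratorError(CgmardError):
    """The synthetic-trace generator could not meet its statistical targets."""


class ConvergenceError(CgmardError):
    """A numerical routine failed to converge."""
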