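"""Exception hierarchy shared across the package.

Three failure kinds cover every contract: malformed external data
(:class:`DataFormatError`), an argument that violates a precondition
(:class:`InvalidArgumentError`) and an operation invoked on an object in the
wrong state (:class:`InvalidStateError`).
"""


class SeedlingNDDError(Exception):
    """Base class for all package errors."""


class DataFormatError(SeedlingNDDError, ValueError):
    """A file or table does not conform to its documented layout."""


class InvalidArgumentError(SeedlingNDDError, ValueError):
    """An argument violates an operation's precondition."""


class InvalidStateError(SeedlingNDDError, RuntimeError):
    """The operation cannot run given the current object state."""


class ConvergenceError(SeedlingNDDError, RuntimeError):
    """A model fit failed in a way that cannot be reported as a flagged fit."""
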