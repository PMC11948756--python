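"""Exception hierarchy used across the package.

All validation and fitting failures derive from :class:`IdpcharError` so
callers (and the CLI) can distinguish package errors from programming bugs.
"""


class IdpcharError(Exception):
    """Base class for all package errors."""


class ValidationError(IdpcharError, ValueError):
    """Input data violates a documented precondition."""


class FormatError(IdpcharError, ValueError):
    """A tabular/FASTA file does not match the expected dialect."""


class FitError(IdpcharError, RuntimeError):
    """A nonlinear fit failed to converge or is degenerate."""
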