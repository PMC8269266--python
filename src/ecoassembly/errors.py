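"""Exception hierarchy.

All user-facing failures derive from :class:`EcoAssemblyError` so callers (and
the CLI) can distinguish bad input from genuine bugs.
"""


class EcoAssemblyError(Exception):
    """Base class for all package errors."""


class FormatError(EcoAssemblyError):
    """A file could not be parsed; the message names the offending row/cell."""


class InvalidArgumentError(EcoAssemblyError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateFitError(EcoAssemblyError):
    """Data admit no informative fit (e.g. every taxon saturates occurrence)."""


class EmptyOutputError(EcoAssemblyError):
    """An operation would return an empty result (e.g. rarefaction depth too high)."""
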