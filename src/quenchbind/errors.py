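"""Exception hierarchy.

All package errors derive from :class:`QuenchBindError` so callers can catch
one base class.  Validation problems (bad inputs, malformed files, bad
configuration) and fit failures are distinguished because the command-line
layer maps them to different exit codes.
"""


class QuenchBindError(Exception):
    """Base class for all errors raised by quenchbind."""


class InputDomainError(QuenchBindError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class FormatError(QuenchBindError, ValueError):
    """A file does not conform to the expected tabular layout."""


class InsufficientDataError(QuenchBindError, ValueError):
    """Too few usable points to perform a fit."""


class ConfigurationError(QuenchBindError, ValueError):
    """Inconsistent or incomplete analysis configuration."""
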