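"""Exception hierarchy.

Validation failures (bad numerics, shape mismatches) raise
:class:`ValidationError`; malformed user configuration raises
:class:`ConfigurationError`; unparseable input files raise
:class:`FormatError`.  The CLI maps all three to exit code 2.
"""


class MSRBFError(Exception):
    """Base class for package errors."""


class ValidationError(MSRBFError, ValueError):
    """Invalid numeric input to an operation."""


class ConfigurationError(MSRBFError, ValueError):
    """Invalid user-supplied configuration; names the offending field."""


class FormatError(MSRBFError, ValueError):
    """Malformed input file; cites the offending row where possible."""
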