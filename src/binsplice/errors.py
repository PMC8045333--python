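"""Exception hierarchy shared across the package.

``ValidationError`` maps to CLI exit code 2, ``StageError`` to 3.
"""


class BinspliceError(Exception):
    """Base class for all package errors."""


class ValidationError(BinspliceError):
    """Malformed or inconsistent input."""


class StageError(BinspliceError):
    """A pipeline stage failed at run time."""
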