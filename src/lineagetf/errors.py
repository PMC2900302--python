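"""Exception hierarchy.

``DataError`` covers malformed or inconsistent input data; ``UsageError``
covers bad invocations (unknown flags, missing config keys). The CLI maps
them to exit codes 2 and 1 respectively.
"""


class LineageTFError(Exception):
    """Base class for all package errors."""


class DataError(LineageTFError):
    """Input data violates a documented precondition."""


class UsageError(LineageTFError):
    """The caller invoked the tool incorrectly."""
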