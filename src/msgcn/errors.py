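"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class MsgcnError(Exception):
    """Base class for package errors."""


class ConfigError(MsgcnError):
    """Invalid configuration: unknown keys, out-of-range options."""


class DataError(MsgcnError):
    """Malformed input data: ragged matrices, missing files, label problems."""
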