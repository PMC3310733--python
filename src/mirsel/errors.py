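"""Exception hierarchy shared across the package.

``DataError`` maps to CLI exit code 1, ``ConfigError`` to exit code 2.
"""


class MirselError(Exception):
    """Base class for all package-specific errors."""


class DataError(MirselError):
    """Malformed, inconsistent or unusable input data."""


class ConfigError(MirselError):
    """Invalid configuration or parameter values."""
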