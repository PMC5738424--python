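"""Exception hierarchy shared across the package.

``ConfigError`` and ``DataError`` map onto the CLI exit codes 2 and 3.
"""


class LesionhubError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(LesionhubError):
    """Invalid parameter or configuration value."""

    exit_code = 2


class DataError(LesionhubError):
    """Input data violates a structural precondition."""

    exit_code = 3
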