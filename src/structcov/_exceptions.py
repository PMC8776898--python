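"""Exception hierarchy shared across the package."""


class StructcovError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(StructcovError, ValueError):
    """Malformed or inconsistent input data (exit code 2 at the CLI)."""


class DegenerateDataError(StructcovError, ValueError):
    """Statistically degenerate input, e.g. zero variance (exit code 1)."""
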