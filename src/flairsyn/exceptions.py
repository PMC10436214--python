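"""Exception hierarchy shared across the package."""


class FlairSynError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(FlairSynError, ValueError):
    """Raised when user-supplied configuration is invalid or inconsistent."""


class DegenerateInputError(FlairSynError, ValueError):
    """Raised when an input is structurally valid but degenerate.

    Examples: a constant volume handed to min-max normalization, an empty
    region mask, an all-zero weight matrix handed to spectral normalization.
    """


class ContractError(FlairSynError, ValueError):
    """Raised when arguments violate an operation's contract (e.g. shape mismatch)."""
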