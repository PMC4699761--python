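"""Exception hierarchy shared across the package."""


class ExenergyError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ExenergyError):
    """A numeral or time token could not be parsed."""


class ValidationError(ExenergyError):
    """An input series or measurement violates a structural invariant."""


class ConfigError(ExenergyError):
    """A configuration object is inconsistent (missing/extra fields for its mode)."""


class InsufficientDataError(ExenergyError):
    """Too few samples remain for the requested computation."""


class DegenerateRecoveryError(ExenergyError):
    """Recovery VO2 never rises above baseline; there is no off-transient to fit."""
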