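"""Exception hierarchy shared across the pipeline."""


class DietvalError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DietvalError):
    """A configuration value is missing, malformed, or inconsistent."""


class ValidationError(DietvalError):
    """Input data violate the expected schema or invariants."""


class FitError(DietvalError):
    """A statistical model could not be estimated (e.g. singular design)."""
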