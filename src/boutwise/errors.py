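"""Exception hierarchy shared across the pipeline."""


class BoutwiseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BoutwiseError):
    """A required configuration value is missing or malformed."""


class ValidationError(BoutwiseError):
    """Input data violate a structural invariant (NaNs, overlaps, bad maps)."""


class ParameterError(BoutwiseError):
    """A numeric parameter is outside its admissible range."""
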