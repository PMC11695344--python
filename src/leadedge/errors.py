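"""Exception hierarchy shared across the pipeline."""


class LeadedgeError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(LeadedgeError):
    """A configuration value is outside its admissible range."""


class FormatError(LeadedgeError):
    """An input file does not conform to its declared schema."""


class ValidationError(LeadedgeError):
    """Data content violates a documented invariant."""
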