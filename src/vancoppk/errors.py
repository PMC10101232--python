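"""Exception types shared across the package."""


class DomainError(ValueError):
    """A covariate or parameter lies outside the model's domain of validity."""


class ConfigurationError(ValueError):
    """A configuration value is structurally invalid (not a modelling issue)."""


class DataError(ValueError):
    """An event table violates the documented dataset contract."""
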