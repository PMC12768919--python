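"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a config object violates its invariants."""


class DomainError(ValueError):
    """Raised when an argument lies outside the modelled domain."""


class EmptyDenominatorError(ZeroDivisionError):
    """Raised when a prevalence or rate is requested over an empty group."""
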