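"""Package-wide exception types."""


class DeepCompartmentError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(DeepCompartmentError, ValueError):
    """A pharmacokinetic parameter, grid or regimen violates its contract."""


class ConfigurationError(DeepCompartmentError, ValueError):
    """An architecture/run configuration is inconsistent."""


class DataError(DeepCompartmentError, ValueError):
    """An event table or dataset violates its invariants."""
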