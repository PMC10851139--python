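"""Exception types shared across the package."""


class FedslideError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FedslideError, ValueError):
    """A configuration object or argument violates its contract."""


class ValidationError(FedslideError, ValueError):
    """An input value is outside its documented domain."""


class ContractError(FedslideError, ValueError):
    """Two objects that must be structurally compatible are not."""


class UndefinedMetricError(FedslideError, ValueError):
    """A metric is requested on inputs where it is undefined (e.g. one class)."""


class UndefinedPredictionError(FedslideError, ValueError):
    """A slide-level prediction is requested for a slide with no usable patches."""
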