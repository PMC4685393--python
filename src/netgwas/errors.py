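"""Exception hierarchy shared across the pipeline stages."""


class NetgwasError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NetgwasError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class DataError(NetgwasError, ValueError):
    """Malformed or inconsistent input data."""


class EmptyNetworkError(DataError):
    """A filtering step removed every edge of the interaction network."""


class EstimationError(NetgwasError, RuntimeError):
    """A statistical estimate could not be computed (degenerate input)."""


class SamplingError(NetgwasError, RuntimeError):
    """A permutation scheme cannot supply enough distinct genes."""
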