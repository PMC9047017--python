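"""Exception hierarchy shared across the pipeline stages."""


class HubfailError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HubfailError, ValueError):
    """A parameter combination is invalid before any computation starts."""


class GenerationError(HubfailError, RuntimeError):
    """The synthetic cohort violated the network-construction rules."""


class ParseError(HubfailError, ValueError):
    """A delimited-text input could not be read (names row/column)."""


class DegenerateDataError(HubfailError, ValueError):
    """A statistical routine received input with no usable variance."""
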