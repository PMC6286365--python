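"""Exception hierarchy shared across the toolkit."""


class QhtsError(Exception):
    """Base class for all qhtskit errors."""


class InvalidParameterError(QhtsError, ValueError):
    """A kinetic or assay parameter is outside its admissible domain."""


class ConfigurationError(QhtsError, ValueError):
    """A generator or pipeline configuration is inconsistent or empty."""


class SchemaError(QhtsError, ValueError):
    """A tabular input does not match its documented schema."""


class InvalidControlError(QhtsError, ValueError):
    """A control measurement required for normalisation is unusable."""


class UndefinedSeparationError(QhtsError, ValueError):
    """Control arms are not separated, so a separation statistic is undefined."""
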