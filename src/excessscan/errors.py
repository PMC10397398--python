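"""Exception hierarchy shared across the pipeline stages."""


class ExcessScanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ExcessScanError, ValueError):
    """An invalid run, simulation, CV or scan configuration."""


class DataError(ExcessScanError, ValueError):
    """Input data violate a stage precondition (negative counts, zero totals, ...)."""


class SchemaError(ExcessScanError, ValueError):
    """Tables disagree on columns, age bands or unit sets."""
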