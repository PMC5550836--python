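"""Exception hierarchy shared across the pipeline."""


class DepmarkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DepmarkError, ValueError):
    """An invalid simulation or pipeline configuration value."""


class DataError(DepmarkError, ValueError):
    """Input data violates a pre-condition (missing samples, non-finite values...)."""
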