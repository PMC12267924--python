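"""Exception hierarchy shared across the pipeline stages."""


class ParadoxFloraError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ParadoxFloraError):
    """An invalid configuration value; names the offending field."""


class InputError(ParadoxFloraError):
    """Malformed or insufficient input data (missing columns, empty tables)."""


class ValidationError(ParadoxFloraError):
    """Input data violating a cross-table contract; carries the offenders."""

    def __init__(self, message: str, offenders=None):
        super().__init__(message)
        self.offenders = list(offenders) if offenders is not None else []
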