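"""Exception hierarchy shared across the package."""


class NeuroAffectError(Exception):
    """Base class for package-specific errors."""


class ConfigError(NeuroAffectError, ValueError):
    """Invalid configuration; the message names the offending field."""


class InputError(NeuroAffectError, ValueError):
    """Invalid data input (wrong shape, missing columns, illegal range)."""


class EstimationError(NeuroAffectError, RuntimeError):
    """A model fit or resampling procedure failed."""
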