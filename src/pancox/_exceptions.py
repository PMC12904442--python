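"""Exception types shared across the package."""


class PancoxError(Exception):
    """Base class for package errors."""


class ConfigError(PancoxError):
    """Invalid configuration; message names the offending field."""


class DataError(PancoxError):
    """Input table violates a schema or value constraint."""


class FitError(PancoxError):
    """A model could not be fit (e.g. no events, empty risk set)."""
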