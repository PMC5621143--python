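"""Exception hierarchy shared across the package."""


class OcweedError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OcweedError):
    """A configuration value is out of its allowed range or inconsistent."""


class ParameterError(OcweedError):
    """An operation parameter is invalid (e.g. even texture window)."""


class InputError(OcweedError):
    """Runtime inputs are malformed or mutually inconsistent."""


class DataError(OcweedError):
    """The data cannot support the requested operation (e.g. too few pixels)."""


class FormatError(OcweedError):
    """A file on disk does not match the expected raster/model format."""


class StateError(OcweedError):
    """An operation was called on a model in the wrong life-cycle state."""


class TrainingError(OcweedError):
    """Iterative training failed (divergence, non-convergence)."""
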