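"""Exception hierarchy for demonsreg.

All library errors derive from :class:`DemonsRegError` so callers (and the
CLI) can catch one base class.
"""


class DemonsRegError(Exception):
    """Base class for all demonsreg errors."""


class DimensionError(DemonsRegError):
    """Shapes of images / fields do not match, or an axis request is invalid."""


class ConfigurationError(DemonsRegError):
    """A parameter value is outside its valid domain."""


class DataError(DemonsRegError):
    """Input data contains non-finite or otherwise unusable values."""


class NumericError(DemonsRegError):
    """A computation produced non-finite values at run time."""


class MetricUndefinedError(DemonsRegError):
    """A similarity metric is undefined for the given inputs (e.g. zero variance)."""


class FormatError(DemonsRegError):
    """A file could not be read or written in the expected image/field format."""
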