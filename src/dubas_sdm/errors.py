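"""Exception types shared across the pipeline."""


class DubasSdmError(Exception):
    """Base class for all package errors."""


class GridFormatError(DubasSdmError):
    """A raster file could not be parsed; the message names the offending field."""


class SchemaError(DubasSdmError):
    """A tabular input is missing required columns or violates its schema."""


class ConfigurationError(DubasSdmError):
    """An invalid configuration value or combination."""


class GeometryError(DubasSdmError):
    """Two grids that must share geometry do not."""


class FitError(DubasSdmError):
    """A model fit could not be carried out (rank deficiency, degenerate data...)."""
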