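"""Exception types shared across the package."""


class NdrError(Exception):
    """Base class for all package-specific errors."""


class RasterFormatError(NdrError):
    """A raster file/table violates the column grammar."""


class RasterValidationError(NdrError):
    """A raster table parses but violates a format invariant."""


class BinningError(NdrError):
    """Invalid binning configuration or incompatible rasters."""


class DataSourceError(NdrError):
    """A datasource specification is infeasible for the binned data."""


class ClassifierError(NdrError):
    """Invalid classifier input (wrong dtype, shape, or degenerate data)."""


class MetricError(NdrError):
    """A result metric was asked for something the predictions cannot supply."""


class ResultsLogError(NdrError):
    """Manifest lookup / save errors."""


class ConfigError(NdrError):
    """A run configuration fails schema validation."""
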