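"""Error taxonomy shared across the pipeline stages."""


class MrtSimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrtSimError, ValueError):
    """A configuration value is missing, unknown, or inconsistent."""


class GeometryError(MrtSimError, ValueError):
    """Inconsistent geometry (e.g. scoring plane upstream of an aperture)."""


class PSFFormatError(MrtSimError, ValueError):
    """A phase-space file could not be parsed."""


class AnalysisError(MrtSimError, ValueError):
    """A dosimetric analysis could not be carried out on the given data."""
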