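"""Exception hierarchy shared across the package.

Every error raised on a user-facing path derives from :class:`LungQuantError`
so the CLI can catch one base class and exit with a structured message.
"""


class LungQuantError(Exception):
    """Base class for all package errors."""


class FormatError(LungQuantError):
    """Input file is not in the expected format (e.g. non-CT DICOM)."""


class GeometryError(LungQuantError):
    """Grid shape/spacing mismatch or inconsistent slice geometry."""


class CalibrationError(LungQuantError):
    """Voxel values are not plausible Hounsfield units."""


class SegmentationError(LungQuantError):
    """Segmentation failed to find a lung-sized structure."""


class ConfigError(LungQuantError):
    """Invalid configuration values (phantom/cohort/run configs)."""


class DomainError(LungQuantError):
    """Argument outside its mathematical domain (stats, classification)."""


class SchemaError(LungQuantError):
    """Tabular input is missing required columns."""
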