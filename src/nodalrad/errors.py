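"""Exception hierarchy shared across the pipeline stages."""


class NodalradError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NodalradError):
    """Invalid configuration value or out-of-range parameter."""


class DegenerateGeometryError(NodalradError):
    """Requested node geometry cannot be represented on the voxel grid."""


class EmptySegmentationError(NodalradError):
    """A segmentation mask contains no voxels."""


class AlignmentError(NodalradError):
    """Feature tables do not align on node identifiers."""


class DegenerateInputError(NodalradError):
    """Input matrix is degenerate (e.g. zero total variance)."""


class DegenerateLabelError(NodalradError):
    """Training labels contain a single class."""


class UndefinedMetricError(NodalradError):
    """Metric is undefined for the given labels (e.g. single-class AUC)."""


class ManifestValidationError(NodalradError):
    """A cohort manifest failed validation; message names the offending row."""
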