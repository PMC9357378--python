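"""Exception hierarchy shared across the pipeline stages."""


class OrganoidMorphError(Exception):
    """Base class for all package errors."""


class ChannelNotFoundError(OrganoidMorphError, KeyError):
    """A requested marker channel is not present in the image stack."""


class InvalidParameterError(OrganoidMorphError, ValueError):
    """A parameter is outside its valid range."""


class DegenerateHistogramError(OrganoidMorphError, ValueError):
    """Automatic thresholding failed because the image is constant."""


class DimensionalityError(OrganoidMorphError, ValueError):
    """An operation received data of the wrong spatial dimensionality."""


class GeometryError(OrganoidMorphError, ValueError):
    """Array shapes or calibrations do not agree."""


class EmptyRegionError(OrganoidMorphError, ValueError):
    """A region of interest contains no voxels."""


class InsufficientDataError(OrganoidMorphError, ValueError):
    """Too few observations for the requested statistic."""


class ConfigurationError(OrganoidMorphError, ValueError):
    """A run configuration is inconsistent or incomplete."""


class PackingError(OrganoidMorphError, RuntimeError):
    """A synthetic field could not be packed within the retry budget."""


class ConsistencyError(OrganoidMorphError, ValueError):
    """Two pipeline artifacts that must describe the same objects disagree."""
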