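"""Exception types shared across the pipeline."""


class HistomilError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(HistomilError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateHistogramError(HistomilError, ValueError):
    """Otsu thresholding received a constant image."""


class FormatError(HistomilError, ValueError):
    """A tile-store container is missing or malformed."""


class ZeroVarianceError(HistomilError, ValueError):
    """A stain-normalization reference has a zero-variance channel."""


class ConfigurationError(HistomilError, ValueError):
    """A model / protocol configuration is internally inconsistent."""


class ManifestError(HistomilError, ValueError):
    """A slide manifest violates an integrity constraint."""


class LeakageError(HistomilError, RuntimeError):
    """Train and test partitions share patients, entities or slides."""


class EmptyStoreError(HistomilError, ValueError):
    """An operation requiring tiles received an empty tile store."""


class BackboneUnavailableError(HistomilError, RuntimeError):
    """The requested feature-extractor backbone cannot be constructed."""
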