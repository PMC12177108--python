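"""Exception hierarchy for the prefulvent pipeline."""


class PrefulError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(PrefulError, ValueError):
    """A parameter violates its documented constraints."""


class FormatError(PrefulError, ValueError):
    """An input file has an unsupported shape or encoding."""


class SegmentationError(PrefulError, RuntimeError):
    """Lung segmentation produced an unusable mask."""


class PhaseEstimationError(PrefulError, RuntimeError):
    """Respiratory phase could not be estimated from the mean lung signal."""


class InsufficientSamplingError(PrefulError, RuntimeError):
    """Too few frames per phase bin to build a composite cycle."""


class UndefinedMetricError(PrefulError, ValueError):
    """A heterogeneity metric is undefined for the given sample."""
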