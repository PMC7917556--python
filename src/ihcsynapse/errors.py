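"""Exception hierarchy for the package.

Every stage raises a subclass of :class:`IHCSynapseError`, so pipeline code
can catch one base class and record per-synapse failures without aborting the
whole run.
"""


class IHCSynapseError(Exception):
    """Base class for all package errors."""


class InvalidProtocolError(IHCSynapseError):
    """Voltage protocol is malformed (empty levels, non-positive rate...)."""


class ParameterError(IHCSynapseError):
    """A model or generator parameter is outside its valid domain."""


class GenerationError(IHCSynapseError):
    """Synthetic scene cannot be rendered (e.g. spot outside the frame)."""


class WindowError(IHCSynapseError):
    """A frame/time window is empty, truncated or out of range."""


class NormalizationError(IHCSynapseError):
    """F0 <= 0 after background subtraction; background region contaminated."""


class FilterError(IHCSynapseError):
    """Filter not applicable at the trace's sampling rate."""


class DegenerateImageError(IHCSynapseError):
    """Image histogram is degenerate (constant image)."""


class SegmentationError(IHCSynapseError):
    """Cell boundary or ROI segmentation produced an empty result."""


class FitError(IHCSynapseError):
    """A curve fit failed to converge or violates its constraints."""


class TableError(IHCSynapseError):
    """Synapse table integrity violation (duplicate ids, too few rows)."""


class UnitError(IHCSynapseError):
    """Unknown unit string passed to a conversion."""
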