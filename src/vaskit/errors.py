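"""Exception hierarchy shared across the toolkit.

Every error raised on bad user input derives from :class:`VaskitError`, so
pipeline code can isolate a failing vessel with one ``except`` clause.
"""


class VaskitError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(VaskitError, ValueError):
    """A parameter violates its documented domain (non-positive size, bad model name, ...)."""


class GeometryError(VaskitError, ValueError):
    """Geometry is inconsistent: ROI outside the image, too few sample points,
    kymograph narrower than the correlation search range, non-positive bed size."""


class BoundsError(GeometryError):
    """An ROI or coordinate falls outside the image bounds."""


class StateError(VaskitError, ValueError):
    """An operation was called on data in the wrong state
    (e.g. velocimetry on a non-normalized kymograph)."""


class DegenerateInputError(VaskitError, ValueError):
    """Input is formally valid but carries no usable signal
    (zero variance after background subtraction, flat intensity profile)."""


class MeasurementError(VaskitError, RuntimeError):
    """A measurement could not be taken (no half-level crossings in a
    diameter profile). Pipelines treat this as 'exclude this vessel'."""


class NoValidTimepointsError(MeasurementError):
    """A velocity trace has no timepoint passing the correlation gate;
    the vessel is excluded, mirroring exclusion of low-contrast recordings."""


class EmptySegmentationError(MeasurementError):
    """No labelled cell survived segmentation and filtering."""


class MaskError(VaskitError, ValueError):
    """ROI/background masks are empty or overlap."""


class PairingError(VaskitError, ValueError):
    """A paired test was requested for groups of unequal size."""


class PlacementError(VaskitError, RuntimeError):
    """Synthetic cells could not be placed without overlap within the retry budget."""


class FitError(VaskitError, ValueError):
    """Too few usable records to fit (fewer than 3 vessels with d, Q > 0)."""
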