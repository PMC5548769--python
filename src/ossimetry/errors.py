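"""Exception hierarchy for the ossimetry pipeline."""


class OssimetryError(Exception):
    """Base class for all pipeline errors."""


class PhantomError(OssimetryError):
    """Phantom construction or erosion failed."""


class ErosionTargetError(PhantomError):
    """Requested porosity change could not be reached.

    Carries the drop actually achieved so callers can diagnose whether the
    target was simply out of reach for the object's internal porosity.
    """

    def __init__(self, target: float, achieved: float, iterations: int):
        self.target = target
        self.achieved = achieved
        self.iterations = iterations
        super().__init__(
            f"BV/TV drop target {target:.4f} not reached after "
            f"{iterations} iterations (achieved {achieved:.4f})"
        )


class GeometryError(OssimetryError):
    """Acquisition geometry is inconsistent with the requested operation."""


class FlatFieldError(OssimetryError):
    """Flat/dark correction impossible (e.g. flat <= dark somewhere)."""


class StitchError(OssimetryError):
    """360-degree stitching could not pair opposing projections."""


class SegmentationError(OssimetryError):
    """Thresholding or labelling failed."""


class AmbiguousOverlapError(SegmentationError):
    """Two reference labels overlap a segmented component equally."""


class MorphometryError(OssimetryError):
    """Morphometric quantity undefined for the requested label."""


class ConfigError(OssimetryError):
    """Invalid or unknown configuration value."""


class StatsError(OssimetryError):
    """Degenerate input to a statistical test."""


class StudyError(OssimetryError):
    """Cohort study could not produce a valid comparison."""
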