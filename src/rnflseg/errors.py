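"""Exception hierarchy for the segmentation pipeline.

Every anticipated failure mode raises a subclass of :class:`RNFLSegError`,
so callers (and the CLI) can distinguish documented segmentation failures
from genuine bugs.
"""


class RNFLSegError(Exception):
    """Base class for all package errors."""


class ImageFormatError(RNFLSegError):
    """Input raster is unreadable, not 2D grayscale, or empty."""


class BoundaryDetectionError(RNFLSegError):
    """No qualifying boundary row found in any column."""


class SegmentationInconsistentError(RNFLSegError):
    """Detected boundaries violate the anatomical ordering (LB above UB)."""


class SnakeDivergenceError(RNFLSegError):
    """Active-contour iteration produced non-finite node positions."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"active contour diverged at iteration {iteration}")


class PhantomLayerError(RNFLSegError):
    """Phantom layer specification yields overlapping or inverted layers."""
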