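"""Grayscale mathematical morphology with the four structuring-element shapes
used by the pipeline: disk(r), rect(width, height), hline(c), vline(c).

Conventions
-----------
* disk(r): all pixels at Euclidean distance <= r from the center of a
  (2r+1) x (2r+1) box.
* rect/hline/vline: odd side lengths only, centered footprints (an even
  length has no center pixel and is rejected).
* Border handling: erosion pads with +inf, dilation with -inf, so opening
  and closing never invent border artifacts.  Reconstruction is geodesic
  within the image domain (no padding).
* complement(f) = 255 - f on [0, 255] data.

Erosion/dilation are flat min/max filters (scipy.ndimage); grayscale
reconstruction iterates geodesic dilation to its exact fixed point
(skimage, 8-connectivity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import reconstruction as _sk_reconstruction


@dataclass(frozen=True)
class StructuringElement:
    """Binary structuring element: a named shape plus its boolean footprint."""

    shape: str
    footprint: np.ndarray = field(compare=False)

    def __post_init__(self):
        fp = np.asarray(self.footprint, dtype=bool)
        if fp.size == 0 or not fp.any():
            raise ValueError("structuring element footprint is empty")
        object.__setattr__(self, "footprint", fp)


def disk(r: int) -> StructuringElement:
    """Disk of radius r pixels (Euclidean distance <= r from the center of a
    (2r+1) x (2r+1) box)."""
    if r < 0:
        raise ValueError("disk radius must be >= 0")
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return StructuringElement(f"disk({r})", yy ** 2 + xx ** 2 <= r ** 2)


def rect(width: int, height: int) -> StructuringElement:
    """Centered rectangle, ``width`` columns x ``height`` rows, both odd."""
    if width <= 0 or height <= 0:
        raise ValueError("rectangle sides must be positive")
    if width % 2 == 0 or height % 2 == 0:
        raise ValueError(f"rectangle sides must be odd, got {width}x{height}")
    return StructuringElement(f"rect({width}x{height})",
                              np.ones((height, width), dtype=bool))


def hline(length: int) -> StructuringElement:
    """Horizontal line of odd ``length`` pixels."""
    if length <= 0 or length % 2 == 0:
        raise ValueError(f"line length must be positive and odd, got {length}")
    return StructuringElement(f"hline({length})", np.ones((1, length), dtype=bool))


def vline(length: int) -> StructuringElement:
    """Vertical line of odd ``length`` pixels."""
    if length <= 0 or length % 2 == 0:
        raise ValueError(f"line length must be positive and odd, got {length}")
    return StructuringElement(f"vline({length})", np.ones((length, 1), dtype=bool))


def _fp(se: StructuringElement) -> np.ndarray:
    if isinstance(se, StructuringElement):
        return se.footprint
    fp = np.asarray(se, dtype=bool)
    if fp.size == 0 or not fp.any():
        raise ValueError("structuring element footprint is empty")
    return fp


def erosion(f: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Flat grayscale erosion, border padded with +inf."""
    f = np.asarray(f, dtype=float)
    return ndi.grey_erosion(f, footprint=_fp(se), mode="constant", cval=np.inf)


def dilation(f: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Flat grayscale dilation, border padded with -inf.

    On a binary mask this expands the support by the structuring element.
    """
    f = np.asarray(f, dtype=float)
    return ndi.grey_dilation(f, footprint=_fp(se), mode="constant", cval=-np.inf)


def opening(f: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Erosion followed by dilation: removes bright details smaller than the
    structuring element.  Anti-extensive and idempotent."""
    return dilation(erosion(f, se), se)


def closing(f: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Dilation followed by erosion: removes dark details smaller than the
    structuring element.  Extensive and idempotent."""
    return erosion(dilation(f, se), se)


def complement(f: np.ndarray) -> np.ndarray:
    """Image negative 255 - f for data in [0, 255]."""
    f = np.asarray(f, dtype=float)
    if f.min() < 0 or f.max() > 255:
        raise ValueError("complement requires intensities in [0, 255]")
    return 255.0 - f


def reconstruct(marker: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Grayscale morphological reconstruction by dilation.

    Iterated geodesic dilation of ``marker`` constrained under ``mask``,
    run to its exact fixed point (8-connectivity).  Restores the full shape
    of every mask object the marker touches.  If floating-point drift left
    marker > mask anywhere, the marker is clipped with a warning.
    """
    marker = np.asarray(marker, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if marker.shape != mask.shape:
        raise ValueError(f"shape mismatch: {marker.shape} vs {mask.shape}")
    if np.any(marker > mask):
        excess = float(np.max(marker - mask))
        if excess > 1e-6:
            warnings.warn(f"reconstruct: marker exceeds mask by up to {excess:.3g}; "
                          "clipping marker to mask", stacklevel=2)
        marker = np.minimum(marker, mask)
    return _sk_reconstruction(marker, mask, method="dilation",
                              footprint=np.ones((3, 3), dtype=bool))
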