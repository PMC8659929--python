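"""Blood-vessel shadow mask.

Retinal vessels run just above the retina and cross the circular scan
perpendicularly, so each vessel casts a dark, nearly vertical shadow column
through the layers below it.  The mask of those shadows is obtained by

1. a zero-phase frequency-domain filter that removes image content with
   nonzero horizontal frequency concentrated near vertical frequency 0
   (i.e. tall vertical bars) while passing everything else, including DC;
2. the positive part of (filtered - original), which lights up exactly the
   pixels darkened by a shadow;
3. morphological cleaning: opening by hline(5), reconstruction under the
   residual, opening by vline(51), restriction to the band between the
   upper RNFL boundary and the lower ONL boundary, a second vline(51)
   opening, and a threshold at 10% of the maximum.

The mask later cancels the snake's external forces inside shadows so the
contours coast smoothly across them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import morpho
from .boundary_detect import rectify_mask
from .errors import SegmentationInconsistentError
from .oct_io import BoundaryCurve, OCTImage


@dataclass
class VesselMask:
    """Binary vessel-shadow mask (1 = shaded pixel) plus the threshold used."""

    mask: np.ndarray
    threshold: float = 0.0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")


def _as_array(I) -> np.ndarray:
    return I.pixels if isinstance(I, OCTImage) else np.asarray(I, dtype=float)


def transfer_function(rows: int, cols: int,
                      sigma_x_cycles: float = 2.0,
                      sigma_y_cycles: float = 6.0) -> np.ndarray:
    """Real zero-phase transfer function H1 of the shadow-suppression filter.

    H1(wx, wy) = 1 - (1 - exp(-wx^2 / 2 sx^2)) * exp(-wy^2 / 2 sy^2),
    a smooth notch that removes energy with |wx| > 0 concentrated near
    wy = 0 while passing the DC bin and all purely vertical variation.
    Widths are given in cycles per image and converted to normalized
    radian frequencies (sx = 2*pi*sigma_x_cycles/cols, likewise sy).
    """
    if sigma_x_cycles <= 0 or sigma_y_cycles <= 0:
        raise ValueError("notch widths must be positive")
    sx = 2 * np.pi * sigma_x_cycles / cols
    sy = 2 * np.pi * sigma_y_cycles / rows
    wx = 2 * np.pi * np.fft.fftfreq(cols)[None, :]
    wy = 2 * np.pi * np.fft.fftfreq(rows)[:, None]
    notch = (1.0 - np.exp(-(wx ** 2) / (2 * sx ** 2))) * np.exp(-(wy ** 2) / (2 * sy ** 2))
    return 1.0 - notch


def suppress_vertical_shadows(I, sigma_x_cycles: float = 2.0,
                              sigma_y_cycles: float = 6.0) -> np.ndarray:
    """Remove vertical-bar content (vessel shadows) in the frequency domain.

    Periodic boundary conditions are exact in x (the scan is circular);
    vertical wrap-around artifacts are tolerated because only a residual is
    extracted downstream.  Output is clipped to [0, 255].
    """
    arr = _as_array(I)
    H1 = transfer_function(*arr.shape, sigma_x_cycles=sigma_x_cycles,
                           sigma_y_cycles=sigma_y_cycles)
    filtered = np.fft.ifft2(H1 * np.fft.fft2(arr)).real
    return np.clip(filtered, 0.0, 255.0)


def shadow_residual(I, filtered: np.ndarray) -> np.ndarray:
    """Magnitude of the negative part of (I - filtered): how much darker each
    pixel is than its shadow-suppressed version."""
    arr = _as_array(I)
    filtered = np.asarray(filtered, dtype=float)
    if filtered.shape != arr.shape:
        raise ValueError(f"shape mismatch: {arr.shape} vs {filtered.shape}")
    return np.maximum(0.0, filtered - arr)


def refine_mask(residual: np.ndarray, ub: BoundaryCurve, ab: BoundaryCurve,
                threshold_frac: float = 0.10,
                open_h: int = 5, open_v: int = 51) -> VesselMask:
    """Morphological cleanup of the shadow residual into a binary mask.

    Keeps only residual structures at least ``open_h`` px wide and
    ``open_v`` px tall inside the row band strictly between the upper RNFL
    boundary and the lower ONL boundary, then binarizes at
    ``threshold_frac`` of the maximum.  A zero pre-threshold image yields an
    empty mask with a warning (no vessels present).
    """
    residual = np.asarray(residual, dtype=float)
    rows, cols = residual.shape
    if np.any(ub.y >= ab.y):
        raise SegmentationInconsistentError(
            "upper boundary must lie strictly above the lower ONL boundary "
            "in every column")

    step = morpho.opening(residual, morpho.hline(open_h))
    step = morpho.reconstruct(step, residual)
    step = morpho.opening(step, morpho.vline(open_v))

    row_idx = np.arange(rows)[:, None]
    band = (row_idx > ub.y[None, :]) & (row_idx < ab.y[None, :])
    step = np.where(band, step, 0.0)

    step = morpho.opening(step, morpho.vline(open_v))

    peak = float(step.max())
    if peak <= 0:
        warnings.warn("vessel mask is empty: no shadow residual survived the "
                      "morphological refinement", stacklevel=2)
        return VesselMask(mask=np.zeros_like(residual, dtype=bool), threshold=0.0)
    thr = threshold_frac * peak
    return VesselMask(mask=step > thr, threshold=thr)


def dilate_mask_for_rectified(mask: VesselMask, shifts: np.ndarray,
                              dilate_h: int = 5) -> VesselMask:
    """Carry the vessel mask into rectified space and widen it horizontally.

    The mask is shifted with the same per-column shifts as the image
    rectification, then dilated by hline(``dilate_h``) so the cancelled zone
    safely covers the shadow flanks.
    """
    shifted = rectify_mask(mask.mask.astype(np.uint8), np.asarray(shifts))
    widened = morpho.dilation(shifted.astype(float), morpho.hline(dilate_h)) > 0
    return VesselMask(mask=widened, threshold=mask.threshold)
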