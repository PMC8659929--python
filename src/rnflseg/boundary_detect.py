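"""Column-wise boundary geometry: signed vertical gradients, windowed
first-crossing selection, circular smoothing, and image rectification.

The scan is periodic in x (it is a closed circle around the optic nerve
head), so curve smoothing and gap interpolation are circular.  The vertical
gradient is the forward difference ``f[r+1, c] - f[r, c]`` stored at row r;
its positive part marks dark-to-bright transitions scanning downward, its
negative part bright-to-dark ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import BoundaryDetectionError
from .oct_io import BoundaryCurve, OCTImage


@dataclass(frozen=True)
class SelectionWindow:
    """Search window for first-crossing boundary selection.

    Per column the search interval is ``[rho + rho1, rho + rho2]`` below the
    reference boundary position rho (the whole column when there is no
    reference).  ``gamma_thr`` is the minimum |gradient| to qualify, and
    ``polarity`` selects dark-to-bright (+) or bright-to-dark (-) edges.
    """

    rho1: int = 0
    rho2: int = 10 ** 9
    gamma_thr: float = 10.0
    polarity: str = "positive"

    def __post_init__(self):
        if not (0 <= self.rho1 < self.rho2):
            raise ValueError(f"need 0 <= rho1 < rho2, got {self.rho1}, {self.rho2}")
        if not self.gamma_thr > 0:
            raise ValueError("gamma_thr must be > 0")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass
class RectifiedImage:
    """Image flattened so a reference boundary becomes a horizontal line.

    ``shifts[k]`` is the integer number of rows column k was moved downward;
    ``reference_row`` is the row at which the reference boundary now sits.
    """

    pixels: np.ndarray
    shifts: np.ndarray
    reference_row: int


def _as_image(f) -> np.ndarray:
    arr = f.pixels if isinstance(f, OCTImage) else np.asarray(f, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2D image")
    return arr


def vgrad(f) -> np.ndarray:
    """Forward-difference vertical gradient, same shape as f (last row 0)."""
    arr = _as_image(f)
    if arr.shape[0] < 2:
        raise ValueError("image needs at least 2 rows for a vertical gradient")
    g = np.zeros_like(arr, dtype=float)
    g[:-1] = arr[1:] - arr[:-1]
    return g


def vgrad_pos(f) -> np.ndarray:
    """Positive part of the vertical gradient (dark-to-bright, downward)."""
    return np.maximum(vgrad(f), 0.0)


def vgrad_neg(f) -> np.ndarray:
    """Negative part of the vertical gradient (bright-to-dark, downward)."""
    return np.minimum(vgrad(f), 0.0)


def first_crossing(gradient: np.ndarray,
                   reference: BoundaryCurve | None,
                   window: SelectionWindow,
                   label: str = "") -> BoundaryCurve:
    """Per column, the first row in the search window whose gradient passes
    the threshold with the window's polarity.

    Columns with no qualifying row are flagged undetected and filled by
    circular linear interpolation between their nearest detected neighbors.
    Raises :class:`BoundaryDetectionError` when no column qualifies.
    """
    g = np.asarray(gradient, dtype=float)
    rows, cols = g.shape
    if window.polarity == "positive":
        qual = g >= window.gamma_thr
    else:
        qual = g <= -window.gamma_thr

    if reference is None:
        lo = np.zeros(cols, dtype=int)
        hi = np.full(cols, rows - 1, dtype=int)
    else:
        rho = np.round(reference.y).astype(int)
        lo = np.clip(rho + window.rho1, 0, rows - 1)
        hi = np.clip(rho + window.rho2, 0, rows - 1)

    y = np.zeros(cols, dtype=float)
    detected = np.zeros(cols, dtype=bool)
    row_idx = np.arange(rows)
    for k in range(cols):
        if reference is not None:
            ref_k = int(round(reference.y[k]))
            if ref_k + window.rho1 > rows - 1:
                continue  # window entirely below the image
        inside = qual[:, k] & (row_idx >= lo[k]) & (row_idx <= hi[k])
        hits = np.flatnonzero(inside)
        if hits.size:
            y[k] = hits[0]
            detected[k] = True

    if not detected.any():
        raise BoundaryDetectionError(
            "no boundary found: no column has a qualifying gradient in the "
            "search window")
    if not detected.all():
        y = _fill_circular(y, detected)
    return BoundaryCurve(y=y, label=label, detected=detected)


def _fill_circular(y: np.ndarray, detected: np.ndarray) -> np.ndarray:
    """Fill undetected entries by linear interpolation on the circle."""
    n = y.size
    idx = np.flatnonzero(detected)
    # unwrap the circle: interpolate on positions extended by one period
    xp = np.concatenate([idx, idx + n])
    fp = np.concatenate([y[idx], y[idx]])
    x = np.flatnonzero(~detected).astype(float)
    # shift query points below the first detected column up by one period
    x_shifted = np.where(x < idx[0], x + n, x)
    filled = np.interp(x_shifted, xp, fp)
    out = y.copy()
    out[~detected] = filled
    return out


def smooth_curve(curve: BoundaryCurve, N: int) -> BoundaryCurve:
    """Circular moving average of odd width N (boxcar low-pass).

    Preserves the curve mean exactly; output is subpixel.
    """
    if N % 2 == 0 or N <= 0:
        raise ValueError(f"window width must be odd and positive, got {N}")
    if N > len(curve):
        raise ValueError(f"window width {N} exceeds curve length {len(curve)}")
    y = ndi.uniform_filter1d(curve.y, size=N, mode="wrap")
    # smoothing mixes interpolated gap values into their neighbors; the
    # result is defined in every column
    return curve.copy_with(y, detected=np.ones(y.size, dtype=bool))


def rectify(I, reference: BoundaryCurve) -> RectifiedImage:
    """Flatten the image so ``reference`` lands on a constant row.

    Each column is shifted vertically by an integer so that the rounded
    reference position moves to ``round(mean(reference))``.  Vacated pixels
    are filled by edge replication; the shifts are kept for mapping curves
    between the two spaces.
    """
    arr = _as_image(I)
    if not reference.detected.all():
        raise ValueError("rectification reference must be fully detected")
    rows, cols = arr.shape
    ref_row = int(round(float(np.mean(reference.y))))
    shifts = ref_row - np.round(reference.y).astype(int)
    out = np.empty_like(arr)
    src = np.clip(np.arange(rows)[:, None] - shifts[None, :], 0, rows - 1)
    out[:] = arr[src, np.arange(cols)[None, :]]
    return RectifiedImage(pixels=out, shifts=shifts, reference_row=ref_row)


def rectify_curve(curve: BoundaryCurve, rect: RectifiedImage) -> BoundaryCurve:
    """Map a curve from original space into rectified space."""
    return curve.copy_with(curve.y + rect.shifts)


def unrectify_curve(curve: BoundaryCurve, rect: RectifiedImage) -> BoundaryCurve:
    """Map a curve from rectified space back to original space."""
    return curve.copy_with(curve.y - rect.shifts)


def rectify_mask(mask: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Apply rectification column shifts to a binary mask (zero fill)."""
    mask = np.asarray(mask)
    rows, cols = mask.shape
    if shifts.shape != (cols,):
        raise ValueError("shift length must equal mask width")
    src = np.arange(rows)[:, None] - np.asarray(shifts)[None, :]
    valid = (src >= 0) & (src < rows)
    out = np.zeros_like(mask)
    cols_idx = np.broadcast_to(np.arange(cols)[None, :], (rows, cols))
    out[valid] = mask[src[valid], cols_idx[valid]]
    return out
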