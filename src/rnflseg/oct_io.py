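"""I/O and coordinate conventions for peripapillary B-scan OCT rasters.

A peripapillary B-scan is a circular OCT section unrolled to Cartesian
coordinates: the x axis is the angular position on the scan circle (periodic),
the y axis is depth into the retina.  Row 0 is the vitreous side and y grows
downward.  This module owns the image/curve containers, the TSNIT sector
<-> pixel-column map, and all file formats (8-bit PNG/TIFF in; CSV boundary
tables, binary mask PNGs and JSON sector reports out).

Columns are 0-based everywhere in memory; the CSV files and the sector map
use 1-based inclusive columns to mirror the device convention.  The
conversion happens here and nowhere else.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ImageFormatError

#: Default axial (depth) scale of the Spectralis peripapillary scan, µm/pixel.
DEFAULT_Z_SCALE_UM = 3.87
#: Default transverse scale for a 3.7 mm scan circle, µm/pixel.  Stored as
#: the device reports it, never derived from the circle geometry.
DEFAULT_X_SCALE_UM = 15.21

#: Canonical TSNIT sector layout: (name, degree_min, degree_max) in scan-circle
#: degrees; each row spans a whole number of 45-degree octants.
_SECTOR_ROWS = (
    ("T", 0, 45),
    ("TS", 45, 90),
    ("NS", 90, 135),
    ("N", 135, 225),
    ("NI", 225, 270),
    ("TI", 270, 315),
    ("T", 315, 360),
)


@dataclass
class OCTImage:
    """2D grayscale OCT raster with physical scaling metadata.

    Parameters
    ----------
    pixels:
        2D float array, intensities in [0, 255]; shape (rows, cols) with rows
        = depth (z, downward) and cols = angular position.
    z_scale_um:
        Axial scale in µm per pixel (must be > 0).
    x_scale_um:
        Transverse scale in µm per pixel (informational only; thickness is a
        purely axial measurement).
    """

    pixels: np.ndarray
    z_scale_um: float = DEFAULT_Z_SCALE_UM
    x_scale_um: float = DEFAULT_X_SCALE_UM

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ImageFormatError(f"expected a 2D image, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise ImageFormatError(f"image too small: shape={self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ImageFormatError("intensities outside [0, 255]")
        if not self.z_scale_um > 0:
            raise ImageFormatError("z_scale_um must be positive")

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BoundaryCurve:
    """Per-column subpixel row position of a layer boundary.

    ``y[k]`` is the boundary position in column k (0-based, row units,
    subpixel).  ``detected[k]`` is False for columns where no qualifying
    edge was found and the value was filled by interpolation.
    """

    y: np.ndarray
    label: str = ""
    detected: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1:
            raise ValueError("boundary curve must be 1D")
        if self.detected is None:
            self.detected = np.ones(self.y.size, dtype=bool)
        else:
            self.detected = np.asarray(self.detected, dtype=bool)
            if self.detected.shape != self.y.shape:
                raise ValueError("detected flags must match curve length")

    def __len__(self) -> int:
        return self.y.size

    def copy_with(self, y: np.ndarray, **kw) -> "BoundaryCurve":
        return BoundaryCurve(y=np.asarray(y, dtype=float),
                             label=kw.get("label", self.label),
                             detected=kw.get("detected", self.detected.copy()))


@dataclass(frozen=True)
class SectorSpan:
    name: str
    degree_min: float
    degree_max: float
    col_min: int  # 1-based inclusive
    col_max: int  # 1-based inclusive


@dataclass
class SectorMap:
    """TSNIT sector layout mapped onto 1-based pixel columns."""

    spans: tuple[SectorSpan, ...]
    cols: int

    #: Sector names in reporting order.
    names = ("T", "TS", "NS", "N", "NI", "TI")

    def columns(self, name: str) -> np.ndarray:
        """0-based column indices belonging to sector ``name`` (union of its
        spans; the temporal sector T wraps around the 0/360 degree seam)."""
        idx = [np.arange(s.col_min - 1, s.col_max) for s in self.spans if s.name == name]
        if not idx:
            raise KeyError(f"unknown sector {name!r}")
        return np.concatenate(idx)


def sector_map(cols: int) -> SectorMap:
    """Linear map of the scan circle [0°, 360°) onto 1-based columns [1, cols].

    ``cols`` must be divisible by 8 so the 45° octant edges land on integer
    column boundaries.  For cols=768 this reproduces the device sector table
    row for row (e.g. Nasal 135°–225° -> columns 289–480).
    """
    if cols <= 0 or cols % 8 != 0:
        raise ValueError(f"cols must be a positive multiple of 8, got {cols}")
    octant = cols // 8
    spans = []
    for name, dmin, dmax in _SECTOR_ROWS:
        c0 = int(dmin / 45) * octant + 1
        c1 = int(dmax / 45) * octant
        spans.append(SectorSpan(name, dmin, dmax, c0, c1))
    return SectorMap(spans=tuple(spans), cols=cols)


# ---------------------------------------------------------------------------
# raster I/O


def read_oct(path, z_scale_um: float = DEFAULT_Z_SCALE_UM, *,
             rgb_policy: str = "reject",
             x_scale_um: float = DEFAULT_X_SCALE_UM) -> OCTImage:
    """Read an 8-bit grayscale PNG/TIFF as an :class:`OCTImage`.

    ``rgb_policy`` controls multi-channel input: ``"reject"`` raises,
    ``"luminance"`` converts with the Rec. 601 weights.
    """
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ImageFormatError(f"cannot read image {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if rgb_policy == "reject":
            raise ImageFormatError(
                f"{path!r} has {arr.shape[-1]} channels; expected grayscale")
        if rgb_policy != "luminance":
            raise ValueError(f"unknown rgb_policy {rgb_policy!r}")
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    if arr.ndim != 2 or arr.size == 0:
        raise ImageFormatError(f"{path!r} is not a non-empty 2D image")
    return OCTImage(pixels=arr.astype(float), z_scale_um=z_scale_um,
                    x_scale_um=x_scale_um)


def write_image(image, path) -> None:
    """Write an image (OCTImage or array in [0,255]) as an 8-bit PNG/TIFF."""
    arr = image.pixels if isinstance(image, OCTImage) else np.asarray(image)
    iio.imwrite(path, np.clip(np.round(arr), 0, 255).astype(np.uint8))


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG (0 / 255)."""
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


# ---------------------------------------------------------------------------
# boundary CSV


_CSV_LABELS = ("UB", "AB", "LB")


def write_boundaries(curves: Sequence[BoundaryCurve], path) -> None:
    """Write boundary curves to CSV: columns x_1based, y_UB, y_AB, y_LB.

    Undetected columns are written as "NA".  Curves are matched to the CSV
    columns by their label; missing labels produce all-NA columns.
    """
    lengths = {len(c) for c in curves}
    if len(lengths) > 1:
        raise ValueError(f"curves have mismatched lengths: {sorted(lengths)}")
    n = lengths.pop() if lengths else 0
    by_label = {c.label: c for c in curves}
    data = {"x_1based": np.arange(1, n + 1)}
    for lab in _CSV_LABELS:
        col = np.full(n, np.nan)
        c = by_label.get(lab)
        if c is not None:
            col = np.where(c.detected, c.y, np.nan)
        data[f"y_{lab}"] = col
    pd.DataFrame(data).to_csv(path, index=False, na_rep="NA",
                              float_format="%.6f")


def read_boundaries(path) -> dict[str, BoundaryCurve]:
    """Read a boundary CSV back into labeled curves."""
    df = pd.read_csv(path, na_values=["NA"])
    out = {}
    for lab in _CSV_LABELS:
        col = f"y_{lab}"
        if col in df:
            y = df[col].to_numpy(dtype=float)
            detected = ~np.isnan(y)
            out[lab] = BoundaryCurve(y=np.where(detected, y, 0.0), label=lab,
                                     detected=detected)
    return out


def write_report(report, path) -> None:
    """Write a sector report (any object with a ``to_dict``) as JSON."""
    with open(path, "w") as fh:
        json.dump(report.to_dict() if hasattr(report, "to_dict") else report,
                  fh, indent=2)
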