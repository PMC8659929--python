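"""Synthetic peripapillary-OCT phantom with exact ground truth.

The phantom emulates the features of a real circular B-scan that drive the
segmentation pipeline: a stack of flat-ish retinal bands (vitreous, RNFL,
GCL+IPL, INL/OPL, ONL, the bright photoreceptor/RPE complex, choroid), a
double-hump RNFL thickness profile peaking in the superior and inferior
octants, vessel-shadow columns that multiplicatively darken everything
below the retinal surface, bright floater artifacts in the vitreous, and
multiplicative speckle noise clip(clean * (1 + n), 0, 255) with n zero-mean
Gaussian of a chosen standard deviation.

Intensities between the RNFL and the photoreceptor band decrease
monotonically, so the only strong dark-to-bright transition below the
surface is the lower ONL edge — the same property of real scans that makes
the windowed first-crossing rule pick the auxiliary boundary.

Boundary ground truth uses the half-open pixel convention: a truth value
y means the interface sits between rows floor(y) and floor(y)+1, i.e.
``y = first_row_of_lower_layer - 0.5``.  Truth curves are returned exactly;
the sd = 0 path is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import PhantomLayerError, RNFLSegError
from .oct_io import BoundaryCurve, OCTImage
from .pipeline import StageConfig, segment


@dataclass(frozen=True)
class Vessel:
    """A vessel shadow: smooth multiplicative attenuation of every pixel
    below the retinal surface across ``width`` columns."""

    center_col: int
    width: int = 10
    attenuation: float = 0.45  # intensity multiplier at the shadow center


@dataclass(frozen=True)
class Floater:
    """A bright disk artifact floating in the vitreous above the RNFL."""

    center_col: int
    center_row: int
    radius: int = 4
    intensity: float = 140.0


@dataclass
class PhantomSpec:
    """Full description of a phantom scan.

    Geometry defaults mirror the study scans (768 x 496 px, 3.87 µm/px
    axial).  Layer intensities and thicknesses are in 8-bit units and pixel
    rows.  The RNFL thickness profile is baseline + amplitude *
    (1 - cos(2 theta - phase)) / 2: a double hump peaking at the superior
    (90°) and inferior (270°) positions of the scan circle.
    """

    cols: int = 768
    rows: int = 496

    # layer intensities, top to bottom
    vitreous_level: float = 15.0
    rnfl_level: float = 170.0
    gcl_ipl_level: float = 120.0
    inl_opl_level: float = 95.0
    onl_level: float = 55.0
    pr_band_level: float = 190.0
    choroid_level: float = 80.0

    # retinal surface (#1-UB) profile: baseline row + one-cycle sinusoid
    ub_baseline: float = 160.0
    ub_amplitude: float = 10.0
    ub_phase: float = 0.7

    # RNFL thickness profile, rows
    rnfl_baseline: float = 20.0
    rnfl_amplitude: float = 12.0
    rnfl_phase: float = 0.0

    # fixed-band thicknesses, rows
    gcl_ipl_thickness: float = 40.0
    inl_opl_thickness: float = 35.0
    onl_thickness: float = 30.0
    onl_amplitude: float = 5.0   # gentle modulation of the ONL depth
    pr_band_thickness: float = 25.0

    vessels: tuple[Vessel, ...] = ()
    floaters: tuple[Floater, ...] = ()
    speckle_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.speckle_sd < 0:
            raise ValueError("speckle_sd must be >= 0")


@dataclass
class PhantomTruth:
    """Exact ground truth of a generated phantom."""

    ub: BoundaryCurve
    lb: BoundaryCurve
    ab: BoundaryCurve
    vessel_mask: np.ndarray


def standard_spec(seed: int = 0, *, speckle_sd: float = 0.05,
                  n_vessels: int = 5, n_floaters: int = 3,
                  cols: int = 768, rows: int = 496) -> PhantomSpec:
    """A phantom in the default study conditions, with vessels and floaters
    placed pseudo-randomly from ``seed``."""
    rng = np.random.default_rng(seed)
    vessels = []
    if n_vessels:
        centers = np.sort(rng.choice(np.arange(int(0.05 * cols), int(0.95 * cols)),
                                     size=n_vessels, replace=False))
        # enforce a minimal gap so shadows stay distinct
        for i, c in enumerate(centers):
            if i and c - vessels[-1].center_col < 25:
                c = vessels[-1].center_col + 25
            vessels.append(Vessel(center_col=int(c),
                                  width=int(rng.integers(7, 15)),
                                  attenuation=float(rng.uniform(0.35, 0.55))))
    floaters = []
    for _ in range(n_floaters):
        floaters.append(Floater(center_col=int(rng.integers(10, cols - 10)),
                                center_row=int(rng.integers(20, 90)),
                                radius=int(rng.integers(3, 6)),
                                intensity=float(rng.uniform(110, 160))))
    return PhantomSpec(cols=cols, rows=rows, vessels=tuple(vessels),
                       floaters=tuple(floaters), speckle_sd=speckle_sd,
                       seed=seed)


def _profiles(spec: PhantomSpec):
    """Integer boundary rows of every band, per column."""
    theta = 2.0 * np.pi * np.arange(spec.cols) / spec.cols
    ub = spec.ub_baseline + spec.ub_amplitude * np.sin(theta + spec.ub_phase)
    rnfl_t = spec.rnfl_baseline + spec.rnfl_amplitude * (
        1.0 - np.cos(2.0 * theta - spec.rnfl_phase)) / 2.0
    onl_t = spec.onl_thickness + spec.onl_amplitude * np.sin(theta + 2.1)

    ub_row = np.round(ub).astype(int)
    lb_row = ub_row + np.round(rnfl_t).astype(int)
    gcl_row = lb_row + int(round(spec.gcl_ipl_thickness))
    inl_row = gcl_row + int(round(spec.inl_opl_thickness))
    ab_row = inl_row + np.round(onl_t).astype(int)
    pr_row = ab_row + int(round(spec.pr_band_thickness))
    return ub_row, lb_row, gcl_row, inl_row, ab_row, pr_row


def clean_image(spec: PhantomSpec) -> np.ndarray:
    """Noise-free phantom raster (deterministic, reconstructible from spec)."""
    ub_row, lb_row, gcl_row, inl_row, ab_row, pr_row = _profiles(spec)
    if (np.any(ub_row < 1) or np.any(lb_row <= ub_row)
            or np.any(ab_row <= inl_row) or np.any(pr_row >= spec.rows - 1)):
        raise PhantomLayerError("layer stack does not fit the image or is "
                                "not strictly ordered")
    r = np.arange(spec.rows)[:, None]
    img = np.full((spec.rows, spec.cols), spec.vitreous_level)
    for top, level in ((ub_row, spec.rnfl_level),
                       (lb_row, spec.gcl_ipl_level),
                       (gcl_row, spec.inl_opl_level),
                       (inl_row, spec.onl_level),
                       (ab_row, spec.pr_band_level),
                       (pr_row, spec.choroid_level)):
        img = np.where(r >= top[None, :], level, img)

    # floaters: bright disks in the vitreous, clipped to stay above the RNFL
    for fl in spec.floaters:
        cc, cr = fl.center_col, fl.center_row
        rr = np.arange(spec.rows)[:, None] - cr
        ccx = np.arange(spec.cols)[None, :] - cc
        inside = (rr ** 2 + ccx ** 2 <= fl.radius ** 2) & (r < ub_row[None, :] - 5)
        img = np.where(inside, np.maximum(img, fl.intensity), img)

    # vessel shadows: smooth multiplicative dimming below the surface
    atten = np.ones(spec.cols)
    for v in spec.vessels:
        half = v.width / 2.0
        x = np.arange(spec.cols) - v.center_col
        profile = np.where(np.abs(x) <= half,
                           np.cos(np.pi * x / v.width) ** 2, 0.0)
        atten = np.minimum(atten, 1.0 - (1.0 - v.attenuation) * profile)
    img = np.where(r >= ub_row[None, :], img * atten[None, :], img)
    return np.clip(img, 0.0, 255.0)


def generate(spec: PhantomSpec) -> tuple[OCTImage, PhantomTruth]:
    """Render the phantom and its exact ground truth.

    Deterministic given ``spec.seed``; the image is
    clip(clean * (1 + n), 0, 255) with n ~ N(0, speckle_sd^2) iid.
    """
    clean = clean_image(spec)
    ub_row, lb_row, _, _, ab_row, _ = _profiles(spec)
    if spec.speckle_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.speckle_sd, clean.shape)
        img = np.clip(clean * (1.0 + noise), 0.0, 255.0)
    else:
        img = clean

    # half-open convention: boundary value = first row of lower layer - 0.5
    ub = BoundaryCurve(ub_row - 0.5, label="UB")
    lb = BoundaryCurve(lb_row - 0.5, label="LB")
    ab = BoundaryCurve(ab_row - 0.5, label="AB")

    # ground-truth shadow: pixels in the UB..AB band dimmed by >= 20
    # intensity units (the contrast at which a shadow is visibly present)
    rr = np.arange(spec.rows)[:, None]
    band = (rr > ub.y[None, :]) & (rr < ab.y[None, :])
    if spec.vessels:
        unshadowed = clean_image(replace(spec, vessels=()))
        vmask = band & (unshadowed - clean >= 20.0)
    else:
        vmask = np.zeros(clean.shape, dtype=bool)

    truth = PhantomTruth(ub=ub, lb=lb, ab=ab, vessel_mask=vmask)
    return OCTImage(pixels=img), truth


def boundary_mae(estimated: BoundaryCurve, truth: BoundaryCurve) -> float:
    """Mean absolute error between two curves, rows."""
    return float(np.mean(np.abs(estimated.y - truth.y)))


def sweep_noise(spec: PhantomSpec, sd_grid, cfg: StageConfig | None = None) -> pd.DataFrame:
    """Run the full pipeline at each speckle level and tabulate boundary MAE.

    Documented segmentation failures are caught and flagged rather than
    raised, so the sweep always completes.
    """
    if len(sd_grid) == 0:
        raise ValueError("sd_grid must be nonempty")
    rows = []
    for sd in sd_grid:
        sp = replace(spec, speckle_sd=float(sd))
        img, truth = generate(sp)
        rec = {"speckle_sd": float(sd), "failed": False, "error": "",
               "mae_ub": np.nan, "mae_lb": np.nan, "G_um": np.nan}
        try:
            res = segment(img, cfg)
            rec["mae_ub"] = boundary_mae(res.ub, truth.ub)
            rec["mae_lb"] = boundary_mae(res.lb, truth.lb)
            rec["G_um"] = res.report.G
        except RNFLSegError as exc:
            rec["failed"] = True
            rec["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(rec)
    return pd.DataFrame(rows)
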