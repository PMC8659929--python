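"""Three-stage RNFL segmentation pipeline and sector thickness report.

Stage order is strictly:

1. #1-UB — upper RNFL boundary: opening by disk(7), positive vertical
   gradient, first-crossing scan, N=101 circular smoothing, snake.
2. #2-AB — auxiliary boundary (lower edge of the ONL): dual
   opening-by-reconstruction cleaning with disk(9), detail removal with
   disk(3), positive gradient, windowed first crossing below #1-UB,
   N=101 smoothing, vessel-shadow mask, snake with mask-cancelled forces.
3. #3-LB — lower RNFL boundary: image rectified on #2-AB, disk(3)
   opening-by-reconstruction in both polarities, closing by a 31-wide
   rectangle and opening by an 11-wide rectangle to bridge vessel shadows,
   negative gradient, windowed first crossing below the rectified #1-UB,
   N=15 smoothing, snake with the rectified mask, mapped back.

The RNFL thickness is w[k] = (LB[k] - UB[k]) * z_scale_um, averaged over
the TSNIT sectors plus the global mean G.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import morpho, snake_freq, vessel_mask as vm
from .boundary_detect import (SelectionWindow, first_crossing, rectify,
                              rectify_curve, smooth_curve, unrectify_curve,
                              vgrad_neg, vgrad_pos)
from .errors import BoundaryDetectionError, SegmentationInconsistentError
from .oct_io import BoundaryCurve, OCTImage, sector_map
from .snake_freq import SnakeParams


@dataclass
class StageConfig:
    """Every tunable of the three stages, defaulting to the published values."""

    # stage #1-UB
    ub_open_radius: int = 7        # disk radius of the initial opening
    ub_threshold: float = 10.0     # first-crossing gradient threshold
    ub_smooth_n: int = 101         # circular boxcar width, columns

    # stage #2-AB
    ab_clean_radius: int = 9       # disk for dual opening-by-reconstruction
    ab_detail_radius: int = 3      # disk for the final open/close pair
    ab_rho1: int = 8               # search window offsets below #1-UB, rows
    ab_rho2: int = 260
    ab_threshold: float = 10.0     # gradient threshold (selection gamma)
    ab_smooth_n: int = 101

    # vessel mask
    vm_sigma_x_cycles: float = 2.0
    vm_sigma_y_cycles: float = 6.0
    vm_open_h: int = 5             # hline opening length
    vm_open_v: int = 51            # vline opening length
    vm_threshold_frac: float = 0.10
    vm_dilate_h: int = 5           # hline dilation in rectified space

    # stage #3-LB
    lb_detail_radius: int = 3      # disk for opening-by-reconstruction
    lb_close_rect: tuple[int, int] = (31, 3)   # (width, height): bridge dark gaps < 31 px wide
    lb_open_rect: tuple[int, int] = (11, 3)    # (width, height): drop bright details < 11 px wide
    lb_rho1: int = 8
    lb_rho2: int = 60
    lb_threshold: float = 3.0      # |gradient| threshold on the negative ridge
    lb_smooth_n: int = 15

    # active contour (shared by all stages)
    snake: SnakeParams = field(default_factory=SnakeParams)

    @classmethod
    def from_dict(cls, d: dict) -> "StageConfig":
        d = dict(d)
        snake_kw = d.pop("snake", None)
        cfg = cls(**d)
        if snake_kw:
            cfg.snake = SnakeParams(**snake_kw)
        return cfg

    @classmethod
    def from_toml(cls, path) -> "StageConfig":
        import tomllib
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lb_close_rect"] = list(self.lb_close_rect)
        d["lb_open_rect"] = list(self.lb_open_rect)
        return d


@dataclass
class SectorReport:
    """Mean RNFL thickness per TSNIT sector plus the global mean, in µm."""

    sectors: dict
    G: float
    w: np.ndarray
    z_scale_um: float

    def to_dict(self) -> dict:
        out = {k: float(v) for k, v in self.sectors.items()}
        out["G"] = float(self.G)
        out["w"] = [float(x) for x in self.w]
        out["z_scale_um"] = float(self.z_scale_um)
        return out


def resolution_limit_um(z_scale_um: float = 3.87, n_boundaries: int = 2,
                        pixel_error: float = 1.0) -> float:
    """Smallest thickness difference resolvable by the image grid.

    With a minimum delineation error of one pixel on each of the two RNFL
    boundaries and an axial scale of 3.87 µm/px, thickness differences below
    2 * 1 * 3.87 = 7.74 µm are not significant.
    """
    return n_boundaries * pixel_error * z_scale_um


# ---------------------------------------------------------------------------
# stages


def segment_ub(I: OCTImage, cfg: StageConfig | None = None) -> BoundaryCurve:
    """Delineate the upper RNFL boundary #1-UB."""
    cfg = cfg or StageConfig()
    I1 = morpho.opening(I.pixels, morpho.disk(cfg.ub_open_radius))
    grad = vgrad_pos(I1)
    window = SelectionWindow(gamma_thr=cfg.ub_threshold, polarity="positive")
    try:
        coarse = first_crossing(grad, None, window, label="UB")
    except BoundaryDetectionError as exc:
        raise BoundaryDetectionError(f"no boundary found for #1-UB: {exc}") from exc
    init = smooth_curve(coarse, cfg.ub_smooth_n)
    return snake_freq.evolve(init, grad, cfg.snake)


def _ab_preprocess(I: OCTImage, cfg: StageConfig) -> np.ndarray:
    """Dual opening-by-reconstruction cleanup for the #2-AB stage."""
    r9 = morpho.disk(cfg.ab_clean_radius)
    r3 = morpho.disk(cfg.ab_detail_radius)
    # remove dark details smaller than disk(9)
    I1 = morpho.complement(I.pixels)
    I3 = morpho.reconstruct(morpho.opening(I1, r9), I1)
    I4 = morpho.complement(I3)
    # remove bright details smaller than disk(9)
    I6 = morpho.reconstruct(morpho.opening(I4, r9), I4)
    # final detail removal with disk(3)
    return morpho.closing(morpho.opening(I6, r3), r3)


def segment_ab(I: OCTImage, ub: BoundaryCurve,
               cfg: StageConfig | None = None) -> tuple[BoundaryCurve, vm.VesselMask]:
    """Delineate the auxiliary boundary #2-AB and the vessel-shadow mask."""
    cfg = cfg or StageConfig()
    I8 = _ab_preprocess(I, cfg)
    grad = vgrad_pos(I8)
    window = SelectionWindow(rho1=cfg.ab_rho1, rho2=cfg.ab_rho2,
                             gamma_thr=cfg.ab_threshold, polarity="positive")
    try:
        coarse = first_crossing(grad, ub, window, label="AB")
    except BoundaryDetectionError as exc:
        raise BoundaryDetectionError(
            f"empty search window for #2-AB: {exc}") from exc
    init = smooth_curve(coarse, cfg.ab_smooth_n)

    filtered = vm.suppress_vertical_shadows(I, cfg.vm_sigma_x_cycles,
                                            cfg.vm_sigma_y_cycles)
    residual = vm.shadow_residual(I, filtered)
    mask = vm.refine_mask(residual, ub, init,
                          threshold_frac=cfg.vm_threshold_frac,
                          open_h=cfg.vm_open_h, open_v=cfg.vm_open_v)
    ab = snake_freq.evolve(init, grad, cfg.snake, mask=mask)
    return ab, mask


def segment_lb(I: OCTImage, ub: BoundaryCurve, ab: BoundaryCurve,
               mask: vm.VesselMask, cfg: StageConfig | None = None) -> BoundaryCurve:
    """Delineate the lower RNFL boundary #3-LB via rectification on #2-AB."""
    cfg = cfg or StageConfig()
    rect = rectify(I.pixels, ab)
    mask_r = vm.dilate_mask_for_rectified(mask, rect.shifts, cfg.vm_dilate_h)
    ub_r = rectify_curve(ub, rect)

    r3 = morpho.disk(cfg.lb_detail_radius)
    # remove dark then bright details smaller than disk(3)
    I1 = morpho.complement(np.clip(rect.pixels, 0, 255))
    I3 = morpho.reconstruct(morpho.opening(I1, r3), I1)
    I4 = morpho.complement(I3)
    I6 = morpho.reconstruct(morpho.opening(I4, r3), I4)
    # bridge vessel shadows: close dark gaps narrower than 31 px, then drop
    # bright details narrower than 11 px
    cw, ch = cfg.lb_close_rect
    ow, oh = cfg.lb_open_rect
    I7 = morpho.closing(I6, morpho.rect(cw, ch))
    I8 = morpho.opening(I7, morpho.rect(ow, oh))

    grad = vgrad_neg(I8)
    window = SelectionWindow(rho1=cfg.lb_rho1, rho2=cfg.lb_rho2,
                             gamma_thr=cfg.lb_threshold, polarity="negative")
    try:
        coarse = first_crossing(grad, ub_r, window, label="LB")
    except BoundaryDetectionError as exc:
        raise BoundaryDetectionError(f"no boundary found for #3-LB: {exc}") from exc
    init = smooth_curve(coarse, cfg.lb_smooth_n)
    # the snake tracks the magnitude of the bright-to-dark transition ridge
    lb_r = snake_freq.evolve(init, -grad, cfg.snake, mask=mask_r)
    lb = unrectify_curve(lb_r, rect)
    lb.label = "LB"

    crossed = np.count_nonzero(lb.y < ub.y)
    if crossed > 0.05 * len(lb):
        raise SegmentationInconsistentError(
            f"segmentation inconsistent: #3-LB above #1-UB in {crossed} of "
            f"{len(lb)} columns")
    return lb


def thickness_report(ub: BoundaryCurve, lb: BoundaryCurve,
                     I: OCTImage) -> SectorReport:
    """RNFL thickness vector and TSNIT sector averages in µm."""
    if len(ub) != len(lb) or len(ub) != I.cols:
        raise ValueError("curve lengths must match the image width")
    diff = lb.y - ub.y
    if np.any(diff < 0):
        raise SegmentationInconsistentError(
            "negative thickness: #3-LB above #1-UB")
    w = diff * I.z_scale_um
    smap = sector_map(I.cols)
    sectors = {name: float(np.mean(w[smap.columns(name)]))
               for name in smap.names}
    return SectorReport(sectors=sectors, G=float(np.mean(w)), w=w,
                        z_scale_um=I.z_scale_um)


def dice(region_a: np.ndarray, region_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|); 1.0 when both empty."""
    a = np.asarray(region_a, dtype=bool)
    b = np.asarray(region_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / float(total)


def rnfl_region(ub: BoundaryCurve, lb: BoundaryCurve, rows: int) -> np.ndarray:
    """Rasterize the RNFL band: pixel (r, k) belongs iff ub[k] < r <= lb[k]."""
    r = np.arange(rows)[:, None]
    return (r > ub.y[None, :]) & (r <= lb.y[None, :])


@dataclass
class SegmentationResult:
    ub: BoundaryCurve
    ab: BoundaryCurve
    lb: BoundaryCurve
    mask: vm.VesselMask
    report: SectorReport


def segment(I: OCTImage, cfg: StageConfig | None = None) -> SegmentationResult:
    """Run the full three-stage pipeline and compute the sector report."""
    cfg = cfg or StageConfig()
    ub = segment_ub(I, cfg)
    ab, mask = segment_ab(I, ub, cfg)
    lb = segment_lb(I, ub, ab, mask, cfg)
    report = thickness_report(ub, lb, I)
    return SegmentationResult(ub=ub, ab=ab, lb=lb, mask=mask, report=report)
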