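# Methods

This note documents the models, parameter choices and numerical decisions
behind `rnflseg`, and what the synthetic phantom does and does not emulate.

## Coordinate and boundary conventions

Row 0 is the vitreous side; y grows downward, so a "positive" vertical
gradient is a dark-to-bright transition scanning down. The vertical gradient
is the forward difference f[r+1,c] − f[r,c], stored at row r. Because that
value describes the interface *between* rows r and r+1, boundary positions
follow a half-pixel convention: a boundary at y means the interface sits
between rows ⌊y⌋ and ⌊y⌋+1. The coarse first-crossing scan returns integer
rows (the row index carrying the gradient value); the snake samples the
ridge with a +0.5 offset so its subpixel equilibrium lands on the physical
interface. Phantom ground truth uses the same convention
(y = first row of the lower layer − 0.5), which makes thickness estimates
unbiased and clean-phantom boundary errors approach zero rather than a
systematic half pixel.

The scan is a closed circle, so everything along x is periodic: curve
smoothing is a circular boxcar, gap filling interpolates around the seam,
and the active contour is closed.

## Morphology

Structuring elements: disk(r) is the exact Euclidean ball of radius r in a
(2r+1)² box; rectangles and lines must have odd sides (a centered origin).
Erosion pads the border with +∞, dilation with −∞, so openings and closings
cannot invent border structure. Grayscale reconstruction is iterated
geodesic dilation under the mask to its exact fixed point, 8-connected, with
no padding; a marker exceeding the mask (floating-point drift after long
operator chains) is clipped with a warning rather than rejected.

For the rectangle notation used in the #3-LB stage, the operative property
is the *horizontal* extent: the closing uses a 31-column × 3-row footprint
(bridging dark gaps narrower than 31 px, i.e. vessel shadows) and the
opening an 11-column × 3-row one (removing bright details narrower than
11 px).

## Active contour

One node per image column, fixed x, deformable y, closed and periodic.
The internal spectrum K(ω) = α(2−2cos ω) + β(2−2cos ω)² is exactly the
eigenvalue spectrum of the circulant α·D2 + β·D4 built from the [−1, 2, −1]
second-difference stencil. The damped inertial update

    (γ + η + K) U_ξ = (γ + 2η) U_{ξ−1} − η U_{ξ−2} + η Q_{ξ−1} F

is DC-neutral (the contour mean is untouched by internal forces) and has
spectral radius < 1 on every non-DC mode, so force-free relaxation converges
to the constant contour at the initialization's mean. Its fixed point is the
static Euler–Lagrange equation K(ω)U = ηQF.

The shape function is the periodic cubic B-spline sampled at the nodes,
(1/6, 2/3, 1/6), whose DFT F(ω) = 2/3 + cos(ω)/3 mildly low-passes the force
term.

External forces are the vertical derivative of the Gaussian-blurred
(σ = 1 row, configurable) ridge map — the positive vertical gradient of the
stage's preprocessed image for #1-UB/#2-AB, the magnitude of the negative
one for #3-LB — sampled bilinearly at each node and zeroed inside the
vessel-shadow mask. The ridge map is normalized to [0, 1] before
differentiation: this bounds the local force slope below the stability limit
of the unit-step iteration for any 8-bit input, so the printed parameter set
(α = 0.5, β = 1, γ = 1, η = 1) is unconditionally usable regardless of image
contrast. Convergence: max per-node displacement < 0.01 rows (tol) or 500
iterations; non-finite states raise an error naming the iteration.

## First-crossing selection and thresholds

Boundary picks are strictly column-wise: the first row inside
[ϱ+ρ₁, ϱ+ρ₂] (below the reference ϱ) whose |gradient| passes the threshold
with the required sign. Published values: ρ₁, ρ₂, γ = 8, 260, 10 for #2-AB
and 8, 60, 3 for #3-LB; the #3-LB mask [−255, γ] with positive printed γ = 3
is read as gradient ≤ −3 (the stage's gradient is negative by construction).
The #1-UB scan threshold is not printed anywhere; the default is 10
intensity units (the same magnitude as the #2-AB selection threshold) and is
configurable. Columns with no qualifying row are flagged undetected and
filled by circular linear interpolation; the subsequent smoothing and snake
own the final position there.

## Rectification

Flattening uses integer per-column shifts (reference row = rounded mean of
the reference boundary) with edge replication, so morphology on the
rectified image stays well defined on 8-bit-like data; curves map between
spaces by adding/subtracting the same shifts (exact round trip). The vessel
mask is shifted with zero fill — replicating a binary mask at the border
would invent shadow pixels — then dilated by a 5-px horizontal line to
cover shadow flanks.

## Vessel-shadow filter

The published description of the shadow-suppression filter is qualitative
(low-pass horizontally, all-pass vertically, DC passed). The implementation
uses the smooth zero-phase notch
H₁(ωx, ωy) = 1 − [1 − exp(−ωx²/2σx²)]·exp(−ωy²/2σy²)
with σx = 2π·2/cols and σy = 2π·6/rows (config-exposed): it removes energy
with nonzero horizontal frequency concentrated near ωy = 0 (tall vertical
bars) without ringing, preserves row means exactly, and makes the final
mask invariant to adding a constant to the image. FFTs use periodic
boundaries — exact in x, tolerable in y since only a residual is extracted.

## Phantom

The generator emulates the features that drive the pipeline: a layer stack
(vitreous 15, RNFL 170, GCL+IPL 120, INL/OPL 95, ONL 55, photoreceptor/RPE
band 190, choroid 80, in 8-bit units) with intensities decreasing
monotonically from RNFL to ONL so the only strong dark-to-bright transition
below the surface is the lower ONL edge (the property of real scans the
windowed first-crossing rule relies on); a smoothly varying surface
(baseline row 160, ±10 rows over one cycle); an RNFL thickness profile of
baseline 20 rows plus a 12-row double-hump modulation,
t(θ) = 20 + 12·(1 − cos 2θ)/2, peaking at the superior and inferior
positions. The modulation is additive (thickness ∈ [20, 32] rows) so the
minimum thickness stays above the ρ₁ = 8 search-window offset — a thickness
range reaching 8 rows would place the #3-LB window start exactly on the
boundary, a degenerate geometry real scans do not exhibit. Vessels
multiply all intensities below the surface by a cos²-tapered attenuation
profile (defaults: 5 vessels, widths 7–14 px, center attenuation
0.35–0.55); floaters are bright disks in the vitreous (radius 3–5 px,
removed by the disk(7) opening); speckle is multiplicative,
clip(clean·(1+n), 0, 255) with n ~ N(0, σ²) i.i.d., σ up to ~0.3 in the
robustness sweep. Vessel-shadow ground truth is the set of band pixels
dimmed by ≥ 20 intensity units.

What the phantom does **not** emulate: correlated (non-white) speckle,
curved-retina geometry, intra-layer texture, motion artifacts, layer
dropout at the image edges, and pathology-driven focal thinning. Passing
phantom tests therefore demonstrates the correctness and internal
consistency of the operators and the pipeline's robustness to the modeled
artifact classes — not clinical-grade accuracy on patient scans, which
requires validation against expert segmentations.

## Problem sizes and defaults in tests

Unit and acceptance tests run the full-resolution 768 × 496 geometry (a
single segmentation takes ~2 s on one CPU). The acceptance script uses ten
seeded phantoms at speckle σ ∈ {0.05, 0.1} with 5 vessels and 3 floaters, a
six-point noise sweep σ ∈ {0, 0.031, 0.1, 0.178, 0.316, 0.5}, and four
structuring-element variants (UB disk 5/9, AB detail disk 1/7) on a clean
phantom. At σ = 0.5 the pipeline is expected to fail with a documented
ordering-violation error — consistent with the observation that boundary
detection breaks down somewhere above σ ≈ 0.316, a noise level outside any
realistic acquisition.

## Known limitations

- The #1-UB scan threshold and the exact vessel-filter transfer function
  are not published; both are principled defaults exposed in the config.
- Scans whose retinal layers are cut off at the image border are a
  documented failure mode (the pipeline raises; clinically such scans are
  re-acquired).
- `first_crossing` returns integer rows; subpixel precision enters only
  through smoothing and the snake.
- The thickness report requires LB ≥ UB everywhere; up to 5 % of crossed
  columns are tolerated inside `segment_lb` but any crossing still fails
  the final report, mirroring the discard-and-reacquire practice.
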