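# Methods

This note documents the models behind each analysis stage, the synthetic
data they are validated against, the tunable parameters and the numerical
choices, and what the passing tests do and do not establish about real
imaging data.

## Kymograph construction and normalization

A kymograph resamples a calibrated (time, y, x) stack along a hand-drawn
center-line polyline: one row per frame, one column per unit of arc length.
Sampling is bilinear (`scipy.ndimage.map_coordinates`, order 1) at 1-px
arc-length steps; manual ROIs are oblique, and nearest-neighbour sampling
would alias streak slopes. Columns are averaged across the ROI thickness
(default 3 µm) at 1-px steps along the local normal, within ±thickness/2.
Coordinates are 0-based, (time, y, x) ordered, pixel centers at integers;
ROI points are (x, y).

Normalization has two steps. First, each position column has its rolling
*temporal* mean subtracted (default window 20 frames). Immobile objects and
static intensity variation along the vessel produce vertical stripes in the
kymograph that equal their own rolling mean, so they vanish, while sloped
streaks of moving cells survive. The window is truncated (shrinking,
symmetric) at the first and last frames rather than padded, so no frames of
a 1-minute recording are discarded; the temporal edges are therefore only
partially background-corrected, and edge-adjacent timepoints should be read
with that in mind. Second, the matrix is standardized to global mean 0 and
standard deviation 1, which makes the correlation gate comparable across
recordings. A rolling mean over time per column (rather than a 2D
neighbourhood) was chosen because the artefact being removed — the vertical
stripe — is constant in time at a fixed position.

## Velocimetry

For each timepoint t a section of `section_frames` rows (default 3) is
examined. For every candidate integer shift s in [−max_shift_px,
+max_shift_px] (default ±15) the Pearson correlation between row pairs one
frame apart, the later row displaced by s, is averaged over the section's
pairs; the correlation is evaluated on a fixed central column window so all
lags use the same sample size. The lag maximizing this mean correlation is
the per-frame displacement; v = Δx/Δt in px/frame converts to µm/s with the
kymograph calibration. "Correlation magnitude" is implemented as this mean
Pearson coefficient because it is bounded in [−1, 1], which gives the 0.8
validity gate a fixed meaning; timepoints at or below the gate carry NaN
velocity and `valid = False`. Ties in the argmax resolve toward the smaller
|s| — under ambiguity the estimator prefers "no flow". Optional three-point
parabolic interpolation around the integer peak (default on) reduces
quantization at sub-pixel speeds; the correction is clamped to ±0.5 px.

Per-vessel summaries report the maximum speed over valid timepoints (the
convention for per-vessel flow velocity), plus the median speed, the valid
fraction, and the number of sign reversals between consecutive valid
timepoints. A vessel with no valid timepoint raises a distinct signal and is
excluded, mirroring the exclusion of low-contrast recordings.

Recovery, measured on synthetic movies at young-like particle density
(8 cells per 100 px): median speed error below max(0.5 px/frame, 10%) for
true speeds 0.5–4 px/frame with ≥ 80% valid timepoints; on pure-noise
kymographs ≥ 90% of timepoints are gated out at 0.8; a two-phase reversal
movie yields exactly one detected reversal.

## Vessel diameter

The minimal projection (per-pixel minimum over time) shows the vessel as a
dark band. The profile along a cross-vessel line (bilinear, thickness-
averaged) is lightly smoothed (3-px moving average) and reduced to a full
width at half minimum: the half level lies midway between the profile
maximum and the *median* of the sub-midlevel values — the absolute minimum
is biased by spots where several dark cells overlapped — and the edges are
the outermost half-level crossings, linearly interpolated, so interior
structure cannot masquerade as a vessel wall. The measurement is invariant
to affine intensity transforms. A flat profile, or one that does not return
above the half level on both sides, raises a measurement failure. A
fully manual mode returns the polyline length as a ruler. At the study
conditions the median recovery error for a 40-px lumen is under 1 px
(worst single seed observed ≈ 1.4 px).

## Volumetric flow and the branching exponent

Q combines the per-vessel maximum speed and diameter under a velocity
profile model: plug (Q = v·πd²/4, default) or Poiseuille (Q = (v/2)·πd²/4,
v read as the centerline maximum of a parabolic profile). Plug is the
default because a single per-vessel maximum speed is reported and any
constant profile factor cancels in the exponent fit; both models are
exposed and the recorded choice travels with the output.

The branching exponent is the slope of ordinary least squares of log Q on
log d across vessels (records with non-positive d or Q are dropped with a
warning; at least three must remain). The fit is exactly invariant to
rescaling Q by a positive constant and recovers the generating exponent of
noise-free Murray trees to better than 1e-6.

## Cell morphometrics

Bright-boundary images are segmented by Otsu thresholding the boundary
ridge, labelling the enclosed dark regions, discarding border-touching
regions (the connected background and truncated cells, whose area and
circularity would be biased) and regions below `min_area_um2`, then
expanding surviving labels ~2 px into the boundary ridge so measured areas
approximate the stained outline. Because labels expand halfway into the
ridge, measured areas on synthetic mosaics run a few percent above the
generating areas; group *comparisons* are unaffected.

Perimeter uses the length of the sub-pixel marching-squares contour after a
5-vertex circular moving average of its vertices. The naive chain-code
perimeter is biased on digitized shapes (a large rasterized disk would
score circularity ≈ 0.91); the smoothed-contour estimator scores a
radius-200 px disk within 1% of 1 and a digitized square within 1% of π/4,
and is monotone in elongation over aspect ratios 1–5. Raw circularity can
slightly exceed 1 on small disks (sub-pixel discretization); both the raw
and the clamped (≤ 1) value are carried per cell. Areas are pixel counts ×
pixel_size². Group comparisons report mean ± SEM per metric with a
two-tailed t-test (paired on request, for matched control-vs-regenerated
designs); spreads are SEM by convention and the output says so.

## Fluorescence (CTF)

CTF = integrated ROI intensity − (ROI area in px × mean intensity of a
user-supplied background-only ROI). "ROI" in the formula is the ROI *area*,
the standard corrected-total-fluorescence convention. The subtraction makes
CTF exactly invariant to a constant offset on the whole image and linear in
multiplicative gain. A helper divides sample CTFs by the mean control CTF
for fold-change reporting.

## Vascular-regression scoring

Bed size is S_vb = p_a − p_b, the ampullae-border perimeter minus the
body-border perimeter — a length, reproduced as the protocol defines it
rather than substituting an area metric. Outlines may be closed polygons
(perimeter = edge-length sum including the closing edge) or precomputed
scalars; the two perimeters must carry the same unit tag, which is never
inferred. Percent regression is 100·(S_ctrl − S_regres)/S_ctrl and may be
negative if the bed grew. Group comparison uses a paired two-tailed t-test
by default (matched colonies before/after treatment).

## Statistics

t statistics are computed from their closed forms (pooled-variance Student,
Welch, and paired designs); two-tailed p-values evaluate the regularized
incomplete beta function I_{df/(df+t²)}(df/2, ½) — no table lookups. Zero
variance with equal means returns t = 0, p = 1 by convention; zero variance
with unequal means is a degenerate-input error. Non-finite values are
rejected, never silently dropped. Under the null the empirical type-I error
at α = 0.05 is 0.05 ± 0.01 over 10,000 simulations. Log-log OLS returns
slope, intercept, slope standard error and r².

## Synthetic data: what it emulates and what it does not

`simulate_vessel_movie` renders a straight horizontal vessel: bright
tunic-like background (level 1.0) with a weak axial gradient, a static dark
lumen band (shading 0.6, antialiased edge exactly at the nominal boundary —
vessels are visibly darker than the tunic even between cell transits),
dark Gaussian blood cells (contrast −0.5, σ = 2 px) advected by a signed
per-frame velocity, immobile speckles that become the vertical kymograph
stripes, and i.i.d. Gaussian noise (σ = 0.02). Particles wrap at the
segment ends so streak density is stationary; a wrapped particle is treated
as a fresh cell entering the segment and is re-drawn at a new transverse
position, which over a recording builds the full lumen coverage a minimal
projection needs. Densities of 8 (young-like) and 2 (old-like) cells per
100 px of vessel length reproduce the dense vs sparse streak textures of
young and old recordings; the default calibration is the reference
acquisition (0.313 µm/px, 0.177 s/frame). Reversal fixtures encode the
velocity as a per-frame signed sequence. All randomness flows from the
explicit per-call seed; identical parameters give bit-identical stacks.

`simulate_murray_network` builds a symmetric c-ary tree (default binary):
children of a segment with diameter d get d·c^(−1/n), so dⁿ is conserved at
every branch point exactly, and each child carries Q/c, conserving flow;
v = Q/(πd²/4). Reported d and v are perturbed by exp(σ·N(0,1)) and the
reported Q is recomputed from the perturbed values. The default root flow
(1.5·10⁴ µm³/s at a 60 µm root) makes the root run at ~3 px/frame under the
reference calibration, so rendered movies stay resolvable at desk-scale
image sizes; the exponent fit is invariant to this scale.

`simulate_cell_mosaic` places non-overlapping ellipses (gamma-distributed
areas with chosen mean and CV; fixed major/minor ratio; random orientation)
by bounded rejection sampling and rasterizes a ground-truth label image plus
a bright-boundary rendering (~2 px ridge over dark interior/background).
Ground-truth circularity uses the exact elliptic-integral perimeter.
`simulate_bed_outlines` builds jittered-ring body/ampullae polygon pairs
whose bed sizes differ by exactly a requested fraction (perimeters scale
linearly under scaling about the centroid, so the fraction is exact).

Deliberately not modelled: pulsatile flow from a beating heart, cell–cell
interactions and non-uniform velocity profiles within the lumen, 3D vessel
geometry, photobleaching, and optics beyond Gaussian blobs. Passing
recovery tests therefore demonstrate correctness of the measurement chain
under controlled conditions — streak contrast, flow steadiness and staining
quality in real recordings can be worse, and the correlation gate and
per-vessel exclusion signals exist precisely to keep such regions out of
downstream fits.

## Problem sizes and numerical choices

Default synthetic movies are 256 frames of 300×(width+16) px; the
full-chain recovery uses 12 vessels of a 5-level tree at 220 frames,
length 256 px. Benchmark replication counts (20 networks for the exponent
recovery, 10,000 null simulations for test calibration, 200–500 Monte-Carlo
replicates for the power-style checks) are the package's reference
configurations. Diameter band edges for velocity comparisons are
closed-open [lo, hi). Velocimetry tie-breaks, the ±0.5 px clamp on
parabolic refinement, the truncated rolling-average window, and the
3-px profile smoothing are fixed, documented constants rather than knobs.

## Known limitations

- The velocimetry search range (±15 px/frame by default) must exceed the
  true per-frame displacement; faster flows need a larger `max_shift_px`
  and a proportionally wider kymograph.
- Per-vessel maximum speed is an extreme-value statistic: with noisy traces
  it runs a few percent above the true steady speed, which propagates to a
  slight downward bias (≈ 0.1) of the end-to-end fitted exponent.
- The FWHM diameter assumes the cross line starts and ends outside the
  vessel and that the lumen is darker than the background.
- Segmentation assumes bright, closed boundaries; gaps merge neighbouring
  cells (no gap-closing morphology is applied).
- Circularity on very small cells (area below ~100 px²) is discretization-
  limited; the raw value is reported alongside the clamped one.
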