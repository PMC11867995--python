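# Methods

`periquant` quantifies where a fluorescently labelled protein sits in a
rod-shaped bacterium — in the cytoplasmic volume or in the periplasmic
envelope — from single-molecule-sensitivity fluorescence image stacks.
Because the analysis must be testable without access to real microscope
data, the package pairs every analysis stage with a synthetic-microscopy
generator whose ground truth serves as the oracle.  This note describes the
models, the defaults and the reasoning behind the open design choices.

## The cell model

A cell is a spherocylinder: a cylinder of length `l − w` with hemispherical
caps of radius `w/2`, total length `l` (2–5 µm) and width `w` (~1 µm).
Its volume is the closed form

    V = π (w/2)² (l − w) + (4/3) π (w/2)³,

which reduces to a sphere (0.5236 µm³ at `w = 1`) when `l = w`.  The
periplasm is modelled as an infinitesimally thin shell at radius `w/2`: the
real envelope is ~20 nm thick, far below the diffraction limit, so a
finite-thickness model would be indistinguishable in the data while
complicating the analytic oracles.  Chained cells (the *tat*-mutant
phenotype) are collinear, abutting spherocylinders whose shell compartments
are treated as contiguous.

## The forward imaging model

Emitters are placed uniformly over the compartment — by volume for
cytoplasmic label, by surface area for shell label — using exact
composition sampling (cylinder vs caps weighted by volume or area).  Each
emitter has an exponential photobleaching lifetime (`bleach_mean_frames`),
truncated below at one frame so every simulated molecule is bright at least
once, and emits a fixed expected photon count per illuminated frame.
Stroboscopic illumination marks a frame "on" when the laser duty cycle
(default 33.3 ms on / 99.9 ms off for tracking, i.e. every fourth frame at
30 Hz) is high at frame start.

Rendering integrates a symmetric Gaussian PSF (σ = 130 nm) over 100-nm
pixels via error functions, then applies the camera model: Poisson shot
noise on signal plus uniform background, gain 1 count/photon, offset 100
counts, Gaussian read noise of 2 counts, clipped at zero.  The emitter's
depth coordinate is carried in the ground truth but ignored in rendering:
~1 µm cells under highly inclined (HiLo) illumination are near-isofocal and
the downstream analysis uses 2D projections only.

Two exact shortcuts keep population-scale studies tractable, both relying
on Poisson additivity and both verified against brute-force rendering in
the test suite:

* `render_summed` draws the time-integrated image in one pass
  (Poisson of the summed rate; read noise scaled by √n_frames);
* `sample_cell_sums` draws the per-frame *whole-cell* integrated intensity
  directly (one draw per frame instead of per pixel), used for gating
  10⁴-cell populations.

Defaults per acquisition follow the study design the package models:
30 Hz, 250 frames.  Two named regimes are used by the validation studies:
the abundant-labelling regime (300 photons/frame, 20 background
photons/px/frame, no bleaching within the acquisition) for per-volume
quantification, and a single-molecule regime (1000 photons/frame, 5
background photons/px/frame, 50-frame mean bleach lifetime).  The
single-molecule numbers encode two physical requirements rather than free
dials: HiLo illumination exists precisely to suppress out-of-focus
background for single-fluorophore detection, and whole-cell gating can
only report occupancy faithfully when one molecule's per-frame photon
budget exceeds a few standard deviations of the no-dye cell-to-cell
spread, which is dominated by real surface-to-volume variation (~2%)
rather than shot noise.  Bleaching well inside the acquisition is required
so that step counting can certify single molecules.

## Segmentation and geometry

Cells are segmented from a 2D reference image (brightfield-like, time-mean,
or time-summed fluorescence) by global Otsu thresholding, morphological
opening, hole filling and connected components, with an area filter
(0.5–20 µm²) and an aspect filter.  Orientation comes from the mask's
second central moments.  Length is the principal-axis extent of pixel
centres plus one pixel — exact on pixel-art rectangles.  Width is the mean
of per-slice orthogonal extents over the cylindrical body: a single global
extent is biased high by ~1 pixel on smooth masks (the extreme pixel
centres graze the outline), while per-slice extents have random alignment
phases whose mean is unbiased and sub-pixel.  Volume errors are dominated
by the width (V ∝ w²); with the slice estimator, rendered cells at
signal-to-background 3 recover volume within a few percent except for
exactly grid-aligned cells, a measure-zero configuration noted as a known
bias.  The width estimator is deliberately not a medial-axis mean: it is
deterministic, exactly testable on rectangles, and documented as biased on
curved (banana-shaped) cells, which are out of scope.

Chains are grouped by mask contact (≤1 px) plus orientation agreement
(<20°); chained cells are analysed per-chain for tracking but excluded
from per-cell ratio statistics unless explicitly enabled, because
segmentation of chains is unreliable — mirroring the workaround of
suppressing chaining biologically when quantifying.

## Per-cell quantification and the ratio statistic

`intensity per volume` (ipv) is the offset-corrected integral of a cell's
pixels divided by its spherocylinder volume.  Three integration images are
used for three purposes: the frame *sum* for quantitative ipv (linear in
photons), the *max projection* for display and spot finding, and the
*peak per-frame* cell sum for single-molecule gating — a molecule bright
for even one frame contributes its whole per-frame budget to that frame's
sum, whereas any time-integrated statistic dilutes short-lived molecules.

Autofluorescence is measured as the mean ipv of no-dye control cells and
subtracted at the ratio stage only (the per-cell distributions are shown
against the baseline as a reference, not baseline-subtracted).  Gating
keeps cells with ipv above baseline + 3 SD of the no-dye distribution.

The central statistic is the background-corrected periplasmic/total ratio.
Per biological repeat r,

    ratio_r = (mean ipv_xc,r − baseline_xc) / (mean ipv_s,r − baseline_s),

where `xc` is the cytoplasm-excluded dye condition and `s` the permeable
dye condition; the pooled estimate is the mean over repeats with a standard
error across repeats (n = 3 in the modelled design — deliberately
low-powered, with a per-cell mode available).  Baselines may be supplied
per repeat; this keeps repeat-level ratios statistically independent,
which the across-repeat standard error assumes, and is how the validation
studies run (a shared pooled baseline correlates the repeats and makes the
nominal interval under-cover).  Repeats whose corrected denominator is
non-positive are flagged and dropped with a warning rather than clipped.
Because the two dyes are not equally bright in cells, the ratio is a
relative, not absolute, periplasmic fraction; an optional brightness
calibration factor is accepted.

## Localization and the peripherality index

Spots are detected per frame as difference-of-Gaussians maxima above
`5 ×` a MAD-based noise scale, with non-maximum suppression within one PSF
radius (2σ) and post-fit de-duplication within 1.5σ.  Sub-pixel positions
come from least-squares fits of a symmetric Gaussian plus constant
background (Gaussian rather than Poisson maximum-likelihood — adequate at
the simulated SNR and pluggable); fits are rejected for non-convergence,
non-positive photons, or σ outside [0.5, 2] × the PSF width.  Empirical
precision matches the Thompson–Larson–Webb shot-noise prediction.

Each localization is projected onto its cell's principal axes and
normalised by the cell dimensions: ξ = along-axis offset / l,
υ = cross-axis offset / w, clipped to [−0.5, 0.5].  The half-width is
taken as w/2 everywhere; localizations in the hemispherical caps, where
that is biased, can be excluded with a flag (the validation studies do).

The short-axis histogram is summarised by the peripherality index P, the
fraction of localizations with |υ| ≥ 0.25.  In the cylindrical mid-section
the projected density of a thin shell is ∝ 1/√((w/2)² − b²), giving
P = 2/3 exactly, and of a uniform volume ∝ √((w/2)² − b²), giving
P = 1 − (√3/2π + 1/3) ≈ 0.391.  P was chosen as the summary statistic
precisely because both limits are analytic, giving a parameter-free
oracle.  Classification thresholds sit midway between the limits:
peripheral at P ≥ 0.55, central at P ≤ 0.45, indeterminate between.
Localization error blurs the shell profile inward, so P degrades
gracefully toward indeterminate rather than flipping class.

Foci (oligomeric assemblies) are accepted spot fits inside the cell (with
a 2 px rim, since membrane spots straddle the outline) whose photons
exceed 5 × the cell's median spot photons, or 5 × the expected
single-emitter photons when fewer than three spots exist.  One focus is
simulated as 10–50 co-located emitters at a membrane point; the real
stoichiometry is unknown, so the count is configurable.

## Traces, the Chung–Kennedy filter and step counting

A spot's trace is the per-frame sum of a 3-px-radius aperture minus the
aperture area times the median of a 4–6 px annulus, so the trace baseline
is zero.  The Chung–Kennedy filter combines a forward predictor (mean of
the W samples before t) and a backward predictor (mean of the W after)
weighted by the inverse p-th power of each predictor's mean squared
prediction error over its last M samples on its own side.  Near an edge
the wrong-side predictor's error explodes and its weight vanishes, so
steps pass through unchanged while flat segments are averaged (≥ 6×, in
practice ~20×, noise-variance reduction at W = 12).  Defaults W = 12
frames (400 ms at 30 Hz), p = 2, M = W; p and M are not fixed by the
modelled design and are exposed in the config.  Windows truncate at the
trace edges; the first and last samples, where one predictor has no data,
pass through unchanged — this keeps molecules that bleach on the second
frame detectable.  A loop-based reference implementation in the test suite
pins the vectorised filter to 1e-9.

Steps are detected on the filtered trace (the filter is what is overlaid
on the data as the fit), with the noise scale estimated from first
differences of the *raw* trace (robust MAD / √2).  A change point is a
position where the difference of flanking window means (up to W each side)
exceeds 3 × the noise scale; candidates closer than W frames merge to the
strongest.  Where a flank is truncated the threshold scales with the
statistic's standard deviation, preserving the false-positive protection
at the trace edges without losing early or late bleach steps.  A trace
certifies a single molecule iff it has exactly one downward step and its
post-step mean lies within 2 × noise of zero.

## Tracking

Localizations are linked greedily frame-to-frame (nearest neighbour under
a distance gate, optional gap bridging); greedy rather than globally
optimal assignment is adequate at single-molecule densities.  Linking and
MSD lags count laser-on frames, with the stride inferred from the smallest
frame spacing, so stroboscopic off-periods are not gaps.  The diffusion
coefficient is the slope of the 1D along-axis MSD over lags 1–4 with a
free intercept (absorbing static localization error), divided by 2Δt.
Mobile molecules on chains diffuse on the chain's lateral surface with
independent Gaussian steps of variance 2DΔt along the axis and around the
circumference, reflecting at the chain ends; a track whose along-chain
range exceeds the longest single cell is flagged as crossing cells —
evidence of a contiguous shell compartment.

## Statistics

Welch's heteroscedastic one-way ANOVA, Welch's two-sided t test, and a
Games–Howell post-hoc (Welch pairwise statistic referred to the
studentized-range distribution at k groups, quantiles computed
numerically via SciPy) operate on repeat-level ratios by default.  Two
algebraic identities pin the implementations: at k = 2 the Welch F equals
the squared Welch t exactly, and the Games–Howell p equals the Welch t p
(q = t√2).  Degenerate inputs (all variances zero, equal means) return
p = 1 by convention with a logged warning.  Stars follow *** p < 0.001,
** p < 0.01, * p < 0.05.

## Validation studies and problem sizes

`periquant.experiments` holds the in silico studies run by both
`tests/test_acceptance.py` and `scripts/acceptance.py`: 10⁵-localization
projection oracles; 200-cell compartment classification at 20 nm
localization error; ratio recovery at labelled fractions 0, 0.05, 0.2 and
1.0 with 3 repeats × 150 cells (100 trials at f = 0 for interval
coverage); filter and step-counting benchmarks (500 traces per
step/noise level, with common random numbers across levels so the
recovery curve is a paired comparison); occupancy recovery on 10⁴ cells
at true occupancy 0.3 against a 1000-cell no-dye control; segmentation
recovery on 64 rendered cells at signal-to-background 3; 100
shell-diffusing tracks at D = 0.1 µm²/s under the 33.3/99.9 ms duty
cycle; and 10⁴-replicate null calibrations of both Welch tests.  In the
occupancy study the gate is computed from sum-level sampling and the
verification trace from an independently rendered realization of the same
ground truth — equivalent to imaging the same cell twice — which leaves
both stages' error rates unchanged.

## What the synthetic data does and does not show

The generator reproduces the geometry, photophysics and noise structure
that the analysis depends on, with matched study designs.  It does not
model focal drift, chromatic effects, blinking/triplet photophysics, 3D
PSF shape, curved cells, cell-to-cell brightness heterogeneity beyond
Poisson statistics, or autofluorescence texture (background is spatially
uniform).  Passing tests therefore demonstrate that the estimators are
correct and calibrated under the stated model, not that real images meet
the model's assumptions; on real data the segmentation, gating threshold
and dye-brightness calibration are the components most likely to need
adjustment.
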