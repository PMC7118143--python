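# Methods

This note documents the models, conventions and numerical choices behind
`shapepath`, the assumptions the synthetic-data generator makes, and
what the tests do and do not establish about real data.

## Coordinate and angle conventions

Positions are 0-based pixel indices in image coordinates (x right, y
down), with continuous centroids at pixel centres. All angles are
reported in the standard mathematical convention — counterclockwise from
+x with y up — obtained by negating dy exactly once, when a displacement
or axis is converted to an angle. Axis-like quantities (ellipse
orientation, axis rotation, accordance) are 180°-periodic and folded to
[−90°, 90°); heading-like quantities (turning angle) are wrapped to
(−180°, 180°]. Frame 0 is t = 42 h after plating and frames are 0.25 h
apart; the first-half window (path fitting) is [42, 47.75] h, the
latter-half window (angle statistics) [48, 54] h. Both windows are
configurable; statistics never mix them.

## Segmentation and ellipse profiling

The single-frame chain is: crop (244 × 244, clamped at borders with the
offset recorded) → Sobel gradient magnitude → threshold (Otsu on the
gradient by default; parameter-free and deterministic) → morphological
closing with a disk of radius 2 → hole filling → connected-component
selection → ellipse fit → QC.

*Object selection.* The component containing the tracked nucleus wins
regardless of size; failing that, the nearest component whose boundary
lies within 10 px of the nucleus. Components under 10 px are ignored; a
frame with no qualifying component is excluded with reason `no-object`.

*Boundary erosion.* The thresholded gradient band straddles the true
intensity boundary by roughly one pixel on each side, so the filled
object systematically overshoots the cell outline — a large relative
error for ~60 px² cell bodies. The selected object is therefore eroded
by `boundary_erosion_px` (default 1) after hole filling. With the
default renderer this makes the segmented pixel count an unbiased
estimate of the true ellipse area (measured bias ≈ −1%, SD ≈ 3%) and
mean orientation error ≈ 3° for elongated cells. The parameter is
config, and 0 disables the correction.

*Ellipse fit.* Axes and orientation come from the eigendecomposition of
the 2 × 2 second central moment matrix of the pixel coordinates (full
axis lengths 4·√eigenvalue — the moments-equivalent-ellipse convention,
identical to `skimage.measure.regionprops`); eccentricity is the
inter-focal distance over the major axis, √(1 − (b/a)²). A collinear
object has minor axis 0 and is excluded as `degenerate`. Solidity is
object pixels over convex-hull pixels; objects strictly below 0.7 are
excluded as `low-solidity` (exactly 0.7 is retained — the threshold is a
strict "below"). An optional manual-exclusion list is honoured with
reason `manual`; no other subjective exclusion exists, so automated runs
are fully deterministic.

## Tracking

Nuclei are detected as connected components above a robust threshold
(median + 6 MAD-sigmas of the frame) with intensity-weighted centroids;
Otsu and absolute thresholds are available but Otsu is unreliable when a
handful of small blobs share the histogram with ~10⁶ background pixels.
Linking is gated mutual-nearest-neighbour between consecutive frames
(gate 15 px), with no gap closing: a missed detection ends the track and
the remainder starts a new one; tracks shorter than `min_track_frames`
(default 40) are dropped. Sparse, slowly moving cells make anything more
elaborate unnecessary, and determinism is worth more here than recall.

Raw positions are smoothed by a centred five-point moving average whose
window shrinks symmetrically at the track ends (length-preserving, exact
on straight constant-speed tracks); movement vectors are forward
differences of the smoothed positions. Frames with a zero movement
vector are flagged invalid and excluded from angular statistics rather
than being assigned an arbitrary heading.

## Projected path

The reference line is fitted to the first-half smoothed positions by
iteratively reweighted least squares with Tukey bisquare weights
(tuning constant 4.685), scale re-estimated each iteration as 1.4826 ×
the median absolute deviation of the residuals, at most 50 iterations,
convergence 1e−8 on the coefficients. Two safeguards matter in
practice:

- the coordinate with larger variance is the regressor, so near-vertical
  paths cannot degenerate;
- the IRLS starts from the Theil–Sen line (median of pairwise slopes),
  not OLS. A redescending loss has local optima, and a gross positional
  outlier can act as a *leverage* point for the chosen regressor; the
  high-breakdown start keeps the fit in the right basin (verified
  against OLS-on-clean-data and statsmodels RLM in the tests).

The direction is signed to agree with the cell's net first-half
displacement. Fewer than 5 points or all-identical points are errors.

## Density surface and summary statistics

The (axis-rotation, turning) pairs enter a product-Gaussian KDE with
bandwidth 20° per dimension, evaluated on a 1° grid over
[−90°, 90°] × [−180°, 180°]. The smoother is deliberately non-periodic
(a plain kernel smoother); mass smoothed past the grid edges is
corrected by renormalising the surface so its trapezoidal integral is 1
(a sub-2% correction for delta-concentrated data, ~1% for typical
dispersions). The peak is read off the grid — with a 20° bandwidth,
sub-degree structure is irrelevant. The accordance rate counts
|accordance| strictly below 15°, over valid records only.

## Group tests

Shape metrics are compared with unpaired two-tailed t tests; an F test
of variance equality at α = 0.05 selects Student's (equal) or Welch's
(unequal) variant. No multiple-testing correction is applied across the
four metrics. Constant-valued metrics short-circuit to t = 0, p = 1.

The two resampling tests draw `resample_size` observations with
replacement from the seed group, recompute the statistic (KDE peak, or
±15° proportion) per trial, and count trials at or beyond the comparison
group's observed value; p = (count + 1)/(trials + 1), so p = 0 is never
reported and the raw count is carried alongside. The resample size
defaults to the comparison group's record count, so the null
distribution reflects that group's sampling noise. The peak test
realises resampling through multinomial count vectors when the seed is
small (one weighted kernel sum per trial) and through index draws when
the seed is large — two exact samplers of the same trial distribution.

*Calibration caveat.* The `direction="auto"` default tests one-sided in
the direction of the observed difference. Under a true null this
data-adaptive choice doubles the one-sided rejection rate (~10% at
nominal 5%), and treating the comparison value as fixed ignores its own
sampling noise. The tests are well calibrated — type-I error 5% ± 2% in
the suite's 500-repetition null studies — when the direction is fixed a
priori and the seed sample is much larger than the comparison sample;
with comparable sample sizes the plug-in p value is anticonservative,
which is a property of this test design, not of the implementation.

## Synthetic-data generator

No imaging data for this assay is deposited, so the generator defines
the study conditions. The model is the simplest one consistent with
shape-coupled persistent migration:

- Cells start near the rim of a circular aggregate (radius 150 px,
  growing with cell count so the sparse-spacing contract stays
  feasible), evenly spaced with small jitter, with an outward radial
  base heading.
- Per frame, the instantaneous heading is the base heading plus
  independent wrapped-normal turning noise (σ_turn), and the step length
  is gamma-distributed (shape 4) around the mean speed, 1.5 px/frame by
  default — a scientist's-choice scale giving ~70 px net outward travel
  over the 12 h window, comparable to the travel visible in published
  trajectory figures; no physical pixel size is defined, so speeds are
  px/frame.
- The cell-body major axis follows the heading of the *five-point
  smoothed* movement plus independent wrapped-normal coupling noise
  (σ_couple), folded to [−90°, 90°). Coupling to the locally averaged
  direction (rather than the frame-to-frame heading) reflects that a
  cell body cannot reorient at 15-minute noise timescales, and makes
  σ_couple exactly the dispersion the downstream accordance statistic
  measures — the property the calibration relies on.
- Shape is drawn once per cell — area ~ N(μ, σ) truncated above 10 px²,
  eccentricity ~ N(μ, σ) clipped to [0, 0.99] — and converted to axes
  via A = πab/4, b/a = √(1 − e²). Area and eccentricity are the sampled
  pair because the four published per-metric means are mutually
  inconsistent under independent axis draws; axis-length recovery is
  therefore not a calibration target. Per-frame shape is constant
  (nothing is known about shape dynamics at this cadence).

Two calibration operations anchor the dispersions to published
statistics: `calibrate_coupling` solves P(|θ| < 15°) = target for a
folded wrapped normal by root finding (e.g. 0.396 → σ ≈ 28.9°, 0.328 →
σ ≈ 35.4°), and `calibrate_peak_density` seeds σ from the closed form
peak = 1/(2π(σ² + h²)) and refines it by simulation against the
pipeline's own grid KDE (8.9 × 10⁻⁵/deg² → σ ≈ 38.1° after refinement).

Rendering places each cell as a brighter elliptical interior with a
darker rim occupying the outer ~1.5 px inside the boundary, on a
mid-grey background with anti-aliased edges, Gaussian noise (SD 3) and
8-bit quantisation; the nuclear channel is a Gaussian blob (SD 2 px,
amplitude 200) per centroid. This dialect was chosen so that a
Sobel-magnitude threshold closes into a single object; all intensities
are config. A rasterisation oracle (`ellipse_mask`) exposes the true
pixel support for recovery tests.

**What the generator does not emulate:** process/neurite morphology,
cell–cell contact and crowding, uneven illumination, phase-contrast
halos, shape dynamics, mitosis, or detection dropouts. Passing tests
demonstrate that the measurement chain is unbiased and well calibrated
under this model — not that segmentation would be unbiased on real
phase-contrast images, where the boundary-erosion compensation would
need re-validation against manual annotation.

## Measurement-route nuances

The accordance-rate and KDE-peak calibrations live at different points
of the chain. Accordance is calibrated through the *full track route*
(generate → smooth → difference → compare with the axis), and the
pipeline recovers the central mass exactly by construction. The KDE-peak
calibration is defined on the *angle-pair level* (independent Gaussian
rotation/turning pairs fed to the pipeline's KDE), as is its recovery
measurement; pushing tracks through the full imaging route instead
yields a higher peak, because five-point smoothing attenuates
frame-to-frame turning noise by roughly √5. Both routes are exercised in
the tests; the distinction is intentional and documented rather than
hidden in a fudge factor.

## Problem sizes and determinism

Default analyses use 24–43 cells × 49 frames; the recovery measurements
use the published record counts (785 and 1032). Resampling defaults are
10,000 (peak) and 1,000 (accordance) trials; the test suite's null
calibration studies use 500 repetitions × 200 trials with seed/
comparison sizes of 4000/200 (accordance) and 3000/100 (peak) — sizes
chosen so the whole suite stays interactive while the binomial
uncertainty on a 5% rate at 500 repetitions (±1% SE) remains well inside
the ±2% acceptance band. Every stochastic component takes an explicit
integer seed; the pipeline writes a manifest with a config hash and
SHA-256 of every artifact, and identical config + seed reproduces
byte-identical outputs.

## Known limitations

- The linker has no gap closing and no split/merge handling; dense
  fields or blinking nuclei will fragment tracks.
- The KDE is non-periodic; dispersions approaching the fold period would
  make edge renormalisation a poor substitute for a wrapped kernel.
- The resampling tests inherit the plug-in anticonservatism described
  above when seed and comparison sizes are comparable.
- Physical units (μm, μm/h) are left to configuration; nothing in the
  pipeline depends on pixel size.
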