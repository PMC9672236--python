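# Methods

## Overview

`gatedqa` scores respiratory-motion-compensation protocols by comparing
each motion-compensated PET image of a phantom against a static reference
acquisition of the same phantom.  Three image-quality axes are quantified
as recovery coefficients (RC = measured / static, ideal 1): segmented
volume, mean activity concentration and cold-rod resolvability.  A
statistics layer (Wilcoxon signed-rank + Bland–Altman percentage analysis)
then decides which protocols perform comparably.  A synthetic study
generator supplies gated phantom images so the whole chain is testable
without scanner access.

## Coordinate and data conventions

Volumes are `voxels[ix, iy, iz]` in Bq/ml with x = left–right,
y = anterior–posterior, z = superior–inferior; z is the motion axis.  All
geometry is in physical millimetres; `origin` is the center of voxel
(0,0,0) and voxel values live at voxel centers.  NIfTI-1 is the canonical
on-disk format (diagonal affine; the acquisition timestamp is carried in
the `descrip` header field); DICOM series directories are read-only, and a
directory holding more than one series is rejected explicitly.  ROI
voxelization uses the voxel-center inclusion rule with no partial-volume
weighting: it converges to the analytic volume as spacing shrinks
(< 1% error at 0.5 mm for a 10 mm-radius sphere) and is exactly testable.

## Reference-ROI propagation

The motion platform translates the phantom rigidly along z, so
registration is deliberately restricted to a 1D z-translation: the mean
axial intensity profiles of static and moving image are cross-correlated
(mean-subtracted, 0.5 mm steps, ±40 mm search).  The returned shift aligns
the moving image onto the reference; ROIs drawn on the static image are
translated the opposite way so they land on the displaced feature.  Hot
targets (spheres, inserts) get a search region — the translated ROI
inflated isotropically by a margin, default 15 mm ≥ half the largest
peak-to-peak motion plus residual — seeded at the regional intensity
maximum.  The triangular cold-rod ROIs are propagated geometrically
without inflation or seeding, since their content is background, not a hot
object.  A constant intensity profile raises "no structure to register";
flatness is judged on the raw in-volume profile, not the zero-padded one.

## Segmentation

Hot objects are segmented by 40%-of-maximum threshold region growing:
the threshold is 0.40 × the maximum *inside the search region* (regional,
not global, so a hotter neighbour cannot poison a target's threshold —
the choice is documented because wording elsewhere is often ambiguous),
inclusion is `>= threshold`, and the region grows 6-connected (faces only)
from the seed.  Failure taxonomy:

* `empty` — the seed itself is below threshold;
* `leak_to_boundary` — the grown region touches the search-region boundary
  (the grid edge counts as boundary);
* `volume_cap_exceeded` — the segmented volume exceeds 5× the reference
  ROI volume (checked when the caller supplies that volume, as the
  pipeline always does).

A failed moving segmentation enters the volume analysis as RC = 5, the
conventional sentinel for gross motion-driven overestimation; a failed
static segmentation is an error, because the reference is then invalid.

Cold rods are the *below*-threshold voxels (`< 0.40 ×` the slice maximum,
strict, mirroring "lower than 40%") of each triangular sector ROI,
evaluated per slice because axial slices can differ in intensity.  Rods
are counted as 4-connected in-plane components with at least
`min_component_voxels` voxels (default 1; raise to suppress noise
speckles); the sector count is the median over the three analysis slices,
rounded half up.  Whether the original methodology pooled the three slices
into one maximum or thresholded per slice is not determinable; per-slice
is implemented and flagged here.  A sector is *distinguished* when at
least 75% of its rods are found.  Sector contrast is the mean of
above-threshold voxels over the mean of below-threshold voxels; it is
undefined (error) for a uniform sector and +inf in the degenerate
noise-free, PSF-free case where the rods are exactly zero.

## Concentration and noise

Mean concentration is averaged under an equal-diameter cylindrical ROI
well inside each insert.  RCs are decay-compensated:
RC = C_mov · 2^(Δt/T½) / C_static with Δt the moving-minus-static
acquisition time.  The half-life defaults to F-18 (6586.2 s) and is
configurable — the isotope's half-life is an experiment property, not a
constant of the method.  The noise figure is the voxel standard deviation
(n−1 denominator) in a ~30 ml VOI placed in the uniform background; the
VOI volume must be within 10% of 30 ml.  "Noise averaged over patterns"
is a report-layer mean of this per-image SD.

## Statistics

The Wilcoxon signed-rank test drops zero differences (Wilcoxon's
convention), assigns average ranks to ties, enumerates the exact null by
dynamic programming for n ≤ 25 (tie-averaged half-ranks are doubled so
sums stay integral) and switches to a tie- and continuity-corrected normal
approximation above.  Two-sided p = 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)), capped at
1.  Bland–Altman percentage analysis: d_i = 100(a_i − b_i)/pair mean;
limits of agreement mean ± 1.96 SD; the CI of the mean uses the
t-distribution because n is small (6–18 in typical use).  A protocol pair
is *comparable* only when both criteria hold: WSRT p above the
Bonferroni-adjusted level (α/m, m = number of pairs actually tested) and
BA CI comprising zero.  Both pooled (across analyses) and per-analysis
views can be produced; the pipeline pools by default.

## Breathing and gating model

Waveforms are sampled at 10 ms.  `sinusoidal` is (A/2)·cos(2πt/T).
`typical` is the cos²ⁿ respiratory model with n = 2:
z = A(cos⁴(πt/T) − ½).  Its flat valley reproduces the end-exhale dwell of
regular patient breathing — the mechanism behind the prospective-exhale
advantage.  With this surrogate the lowest quarter of the range holds
exactly half of each cycle (a closed-form property of cos⁴); the tested
property is the dwell *asymmetry* — far more time at end-exhale than at
end-inhale.  `irregular`
jitters per-cycle period and amplitude lognormally (σ = 0.15, seeded).
Hysteresis is a loop of the requested width (default 3 mm where used) on a
secondary in-plane axis, 90° out of phase; its image effect is a small
extra blur.  Defaults follow the study conditions this package emulates:
periods 4–5 s, peak-to-peak 28 mm (sinusoidal) / 25 and 23 mm (typical).

Cycles are the intervals between consecutive interior maxima (peak
prominence > 10% of amplitude).  Irregular-cycle rejection keeps cycles
whose duration is within a relative tolerance of the mean (typical
settings 0.12–0.50).  Prospective windows start `trigger_delay` (default
0.28 s; a rounded 0.3 s appears in some summaries) after the cycle's
end-inhale maximum or end-exhale minimum and last `window_fraction` of the
cycle, truncated with a warning at the cycle end.  Retrospective gating
splits each cycle into N equal time bins from its first maximum.  Each
protocol reduces to one displacement kernel per image: a 1 mm-binned
histogram of z over the accepted time (bin centers on integer mm so
whole-voxel shifts stay exact), plus the duty cycle measured against the
time spanned by the detected cycles — hence retrospective phase duties
partition to 1 when nothing is rejected.  A zero-amplitude waveform yields
delta kernels at 0 mm directly, since a flat trace has no detectable
cycles.

Observed and intended: exhale kernels are tighter than equal-width inhale
kernels for 20% and 30% windows; at 40% the window overruns the exhale
plateau into the steep rise and the advantage disappears — consistent with
mid-width exhale gating being the best-performing protocol family.

## Synthetic phantoms and forward model

Three digital phantoms (activity maps on a ≤ 1 mm grid):

* **Body phantom** — six hot spheres (0.52, 1.15, 2.57, 5.57, 11.49,
  26.2 ml) at 80 kBq/ml on a 114.4 mm circle in a 15 kBq/ml cylindrical
  background; a 30 ml central sphere serves as the noise VOI.
* **Insert phantom** — six refillable 30 mm-diameter cylinders (three
  33 ml, three 11 ml) at 900 kBq/ml in a cold body; density metadata is
  out of scope because the analysed images are attenuation-corrected by
  assumption.
* **Cold-rod phantom** — six 60° sectors of solid rods (diameters 4.8,
  6.4, 7.9, 9.5, 11.1, 12.7 mm) in a 7 kBq/ml background.  Rod centers sit
  on a triangular lattice with pitch 2× diameter (the standard cold-rod
  convention), inner margin 12 mm, outer radius 80 mm; the per-sector
  counts the lattice yields are recorded as ground truth in the study
  manifest rather than imposed.

The forward model is kernel convolution: weighted z-shifts of the activity
map (exact slice moves for whole-voxel offsets), isotropic Gaussian PSF
(default FWHM 4.7 mm), resampling to the acquisition voxel size (2 mm
static, 4 mm gated; a Gaussian anti-alias prefilter keeps total activity
conserved within 2% when downsampling), optional physical decay over the
acquisition offset, and Poisson noise with expected per-voxel counts
value(kBq/ml) × voxel volume(ml) × sensitivity × duty cycle × acquisition
time.  The sensitivity default (0.5 counts per kBq·s per ml) was set by a
forward calculation so a 14-minute gated acquisition of the 15 kBq/ml
background at 4 mm voxels lands in the ~10% relative-noise regime typical
of such scans.  No sinogram formation, reconstruction, scatter, randoms or
attenuation artifacts are simulated: kernel convolution is sufficient to
exercise every QA metric, but it cannot reproduce reconstruction-specific
effects (iteration-dependent resolution, noise correlations), so passing
tests validate the analysis chain and the motion/duty-cycle physics — not
any particular scanner's absolute numbers.  Deformable (organ-like) motion
is likewise out of scope: the platform moves the whole phantom rigidly.

## Pipeline

`run_qa` executes simulate → propagate → segment → metrics → compare →
report from a YAML-able config, deterministically given config + seed (all
randomness funnels through one seeded generator; reports are written with
fixed float formatting so identical runs are byte-identical).  Individual
segmentation failures are logged and recorded, never fatal.  Retrospective
protocols are summarized by averaging RCs over phases before pooling.
Ranking is per analysis by |mean RC − 1| with smaller SD breaking ties
(scores rounded to 9 decimals so analytically equal means are not ordered
by float noise); the overall rank averages the per-analysis ranks, and
ties are reported rather than silently broken.

## Problem sizes and defaults used in shipped runs

Shipped tests and examples run the body phantom at 1–2 mm build
resolution, studies with 10–20 breathing cycles, and noise replicates of
20 — sizes chosen to keep a desk-scale iteration loop while leaving every
mechanism (partial volume, duty cycle, dwell asymmetry, decay
compensation) observable.  The trend observed at these sizes — RC_CA
decreasing monotonically with amplitude, small inserts losing more than
large, noise scaling as 1/√duty — are resolution-independent mechanisms,
verified as such by the property suite.

## Known limitations

* 1D translation-only registration: correct for a rigid platform, wrong
  for deformable motion.
* The cos⁴ surrogate approximates proprietary patient traces; real typical
  patterns differ in detail (users can supply CSV waveforms).
* The 40% rule uses the regional maximum; methodologies using a global or
  background-relative threshold will differ on low-contrast targets.
* Rod counting is sensitive to `min_component_voxels` on noisy images.
* Amplitude-based gating is not implemented (time-based protocols only).
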