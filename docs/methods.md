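# Methods

## Signal model

Each pixel's temporal AF profile under continuous excitation is modeled as a
single-exponential photobleaching decay

I(t) = A·exp(−t/τ) + C,

with bleaching amplitude A ≥ 0 (intensity units), decay constant τ > 0
(seconds) and residual plateau C ≥ 0. The model assumes a single dominant
bleachable fluorophore pool per pixel, time-invariant illumination, and no
inter-pixel coupling; linear and double-exponential comparators are kept
for model selection only. Acquisition is emulated as 8-bit frames at a
fixed frame interval (default 1 s, 20 frames), with the AF signal in the G
channel of RGB input. Timestamps are index·interval with t = 0 at the
first frame, which anchors AF₀ = I(0).

## Per-pixel fitting

Bounded nonlinear least squares (scipy `least_squares`, trust-region
reflective, analytic Jacobian). Defaults, all configurable via
`FitSettings`:

* bounds: A, C ∈ [0, 4·max(I)]; τ ∈ [frame_interval/10, 50·duration];
* initialization: A₀ = max(I(0) − I(end), ε), C₀ = max(I(end), ε),
  τ₀ = duration/3 — scale-aware and convergent for monotone decays;
* convergence tolerances 1e−12 so that noiseless inputs refit to machine
  precision;
* plain squared loss (robust losses configurable but off by default).

Status handling: a curve that is constant zero or constant at the
saturation level, or whose optimizer fails, is **unfittable** and carries
the sentinel (A, τ, C) = (0, 0, 0). A converged fit is **poor** —
excluded from the maps along with unfittable pixels, though its values are
retained in the per-pixel record — when τ pins at its upper bound, when
A + C > 2·max(I), when the input was a nonzero constant (decay
unidentifiable), or when the residual sum of squares exceeds the curve's
total sum of squares about its mean (i.e. the fit is no better than a flat
line). The validity mask marks exactly the ok pixels; all excluded pixels
are zero in every parameter map.

`fit_stack` loops the same per-pixel routine over the image (identical
results to calling `fit_pixel` pixel-by-pixel), fills AF₀ from the raw
first frame regardless of fit outcome, and records the frame interval,
model and settings in the map metadata.

Model comparison fits the linear (2 parameters), single-exponential (3) and
double-exponential (5, components sorted τ₁ < τ₂) models and ranks them by
AICc; residual sums of squares are floored at a tiny scale-relative value
so that noiseless data do not produce log(0), which also makes the
lower-parameter model win ties, as it should.

Known estimator property: for pixels whose true τ is far above the
acquisition duration the decay is nearly linear and τ is weakly identified;
fitted τ then has a long right tail (bounded by τ_max). Region means are
mildly biased upward by this tail; medians are robust to it.

## Stabilization

Motion is modeled as a global per-frame translation (the minimal model for
a contact-positioned probe over 20 s); the reference is frame 0. The
estimator is two-pass phase correlation: (1) integer shift from plain phase
correlation; (2) subpixel refinement (default resolution 0.1 px) on
demeaned, Hann-windowed, integer-corrected frames — the window suppresses
the wrap-around edge mismatch that otherwise biases upsampled correlation
toward zero. Both frames are median-prefiltered (3×3) for estimation only:
static defects (dead sensels, saturated glare) do not move with the tissue
and would anchor the correlation at zero shift. Estimates at or below the
subpixel resolution are treated as zero rather than resampled, so a
drift-free stack passes through bit-identically. Frames are resampled by
linear interpolation (no overshoot on 8-bit data); pixels that read outside
the field of view in any frame are flagged invalid, never zero-filled, and
the invalidity propagates into the fit mask. The per-frame residual metric
is 1 − normalized cross-correlation against the reference; it is nonzero
even for perfectly aligned frames because bleaching changes frame content,
and NaN flags a constant frame that could not be registered.

## Phantom generator

The simulator emulates: per-region single-exponential kinetics with smooth
spatial parameter variation (Gaussian random fields, correlation length
2 px, pointwise SDs per region); an elliptical tumor core with a junction
annulus obtained by morphological dilation (default 8 px); shot noise
(Gaussian with SD = scale·√signal, default scale 0.5) plus additive read
noise (default SD 2) — a standard CMOS model; global rigid drift
(per-frame (dy, dx), linear resampling); round-half-up 8-bit quantization;
and a defect fraction (default 1%) of pixels constant at zero or at
saturation across all frames. Ground truth (A/τ/C maps and a
skin/junction/core/defect label map) is emitted alongside every stack.

Tissue-class presets encode qualitative contrasts only: skin
(A = 120, τ = 10 s, C = 70), sporadic-BCC core (60, 6, 40), NBCCS core
(55, 9.5, 40 — kinetics nearly indistinguishable from skin, by design),
SCC core (65 ± 25, 4 ± 2, 45 ± 15 — steepest decay, largest intra-core
SDs). Junction parameters default to the core/skin midpoint. These numbers
are inventions chosen to express the orderings a clinician would recognize
(tumors darker than skin; sporadic BCC and SCC bleach faster; NBCCS τ near
skin; SCC most heterogeneous); no measured per-class values exist.

What the phantoms do **not** emulate: wavelength-dependent optics
(melanin/hemoglobin absorption, depth-resolved transport), structured
specular glare, illumination inhomogeneity, non-rigid motion, or
patient-level covariates (age, site, phototype). Passing tests therefore
demonstrate correctness of the algorithms under the stated acquisition
model, not clinical performance on real lesions.

## Segmentation and region designation

SLIC superpixels (scikit-image) on min–max-normalized maps; defaults
n_segments = 300 at full 466×448 resolution (scaled to ~60–120 on reduced
phantoms so superpixels stay small relative to lesions), compactness 0.1.
Designation is driven by one map (default AF₀): with skin reference
(mean, SD) from an explicit mask or, by default, the outer 15% border band
(lesions are centered by acquisition design), each superpixel's z-score is
computed from its mean over valid pixels; |z| ≥ 3 → core, core-adjacent
(8-connectivity) with |z| ≥ 1.5 → junction, else skin; superpixels with
under 50% valid pixels are excluded. Thresholds are deliberately
configurable — lesion presentation varies too much for universal values.
Designations are invariant under affine rescaling of the driving map. A
manual ROI label image (0 = skin, 1 = junction, 2 = core) can replace the
automatic rule entirely.

## Cohort statistics

The observation unit is the per-lesion region mean (inner = core
superpixels, junction, skin) of each parameter — pixels within a lesion
are spatially autocorrelated and would wildly overstate n. Homogeneity is
checked with Levene's test (group-mean centering; the statistic is a
one-way F on absolute deviations, so equal constant spreads give W = 0 and
zero within-group spread with unequal between-group spreads gives W = ∞,
while all-zero deviations are rejected as undefined). Group differences
use Kruskal–Wallis with tie correction; pairwise contrasts use Dunn's test
on pooled midranks with tie correction and Bonferroni adjustment
(p_adj = min(1, m·p), m = k(k−1)/2). Significance stars follow the
conventional 0.05/0.01/0.001 ladder. Both rank statistics are
cross-checked in the test suite against brute-force implementations written
directly from the rank definitions.

A statistical property worth stating: the family-wise null rejection rate
of the Bonferroni-adjusted Dunn procedure is conservative — with three
groups of n = 15 it simulates to ≈ 0.038 at α = 0.05, below the nominal
level, because the three pairwise rank statistics are positively dependent.
This is the expected behavior of Bonferroni, not an implementation defect;
the per-test procedures (Levene, Kruskal–Wallis) simulate to 0.045–0.056.

## Boundary-mismatch analysis

Masks are derived from mask-aware Gaussian-smoothed maps (σ = 2 px;
normalized convolution so sentinel zeros never leak) because per-pixel τ
estimation noise otherwise dominates the pixel-level z-statistic. The AF
mask thresholds below the skin reference; the kinetic mask is two-sided.
Thresholding defaults to Otsu's bimodality threshold on the z-deviation
map, with the z-threshold (default 3) acting as a lesion-presence guard —
an empty mask is returned flagged when the peak deviation never reaches
it. The rationale: a fixed z cut lands at different points of the
boundary ramp on maps with different contrast-to-noise (the AF z-peak is
typically ~3× the τ z-peak), which systematically biases between-map area
comparisons; the Otsu cut lands at the ramp midpoint irrespective of
contrast scale, and on phantoms with coincident AF/kinetic lesions it
restores area ratios within a few percent of 1. The fixed-z rule remains
available (`threshold_mode="fixed"`). After thresholding: largest
connected component, then morphological closing (disk radius 2).
Comparison metrics: pixel areas, area ratio (kinetic/AF), Dice
2|X∩Y|/(|X|+|Y|), and the symmetric mean nearest-neighbor distance
between mask perimeters in pixels.

No histologic-margin correspondence is claimed anywhere; the boundary
metrics quantify mismatch between two image-derived contours only.

## Pipeline and reproducibility

`run_pipeline` executes acquire → stabilize → fit → segment → summarize →
boundary with validated configuration (YAML-loadable), structured logging,
and a JSON manifest containing all settings, the shift trace, and SHA-256
checksums of every stage's arrays; identical config + seed reproduces
bit-identical checksums. Stage failure halts the run, retains partial
outputs, and records the failing stage in the manifest.

## Problem sizes used for validation

Full acquisition size is 466×448; validation simulations are run at
reduced sizes chosen to keep the whole suite comfortably fast while leaving
every region hundreds to thousands of pixels: exact noiseless recovery at
128×128; multi-seed noisy recovery at 48×48 over 20 seeds; the three-class
cohort at 64×64 with 15 lesions per class (per-lesion geometry jitter,
independent noise realizations); boundary phantoms at 96×96; null
simulations at 10,000 replicates. Scaling in lesion count and pixels per
region, not image area, is what the statistics consume, so these sizes do
not change any conclusion.

## Known limitations

* Translation-only motion model; no deformable registration or
  illumination-drift correction.
* τ is weakly identified when the true decay is much slower than the
  acquisition window (right-tailed τ estimates; medians preferred for
  robust summaries).
* The junction designation depends on superpixel adjacency and can be
  empty for small lesions at coarse superpixel sizes.
* Phantom realism limits listed above; in particular no optical forward
  model, so absolute parameter values carry no physical meaning.
* No patient-level clustering in the statistics (one lesion = one
  observation), matching the intended use on cohorts of independent
  lesions.
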