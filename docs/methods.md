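# Methods

This note records the models, estimators, parameter choices, and known
limitations behind `fadynamics`, in the order data flows through the
package.

## Synthetic data: what it emulates, and what it does not

All validation rests on seeded generators with ground truth. They are
designed to reproduce the *statistical structure* each analysis stage
assumes — not photorealistic microscopy.

**FA images** (`synthetic.generate_fa_image`). Cells are non-overlapping
nuclei (Gaussian blobs) with adhesions placed in an annulus near the
cell edge, reflecting the peripheral location of focal adhesions.
Adhesions are anisotropic 2-D Gaussian spots with aspect ratio uniform
in 1–4, oriented roughly tangent to the cell border. True areas are
log-normal in μm² (default μ = 0, σ = 0.5 in log-space, i.e. median
1 μm²); the distribution family is an assumption — the real FA-size
distribution is not known in closed form, and log-normal was chosen as
the standard positive, right-skewed model. A per-condition multiplier
scales areas *after* drawing, so paired conditions share geometry
exactly and the planted effect size is exact (mean ratio = multiplier).
Adhesions keep a 3 μm minimum pairwise separation: focal adhesions are
discrete structures, and without the constraint overlapping Gaussian
spots merge at segmentation and recall measurements confound the
segmenter with the renderer. Noise is Poisson shot noise (peak photon
count = snr²) plus unit-variance Gaussian read noise — the simplest
two-component CCD model. Default pixel size 0.339 μm/px makes
4 px = 0.46 μm².

The nocodazole assay is encoded as per-gene multipliers for the three
conditions, with (1.0, 1.6, 1.1) as the normal response: microtubule
depolymerization enlarges adhesions ~1.6-fold and washout returns them
near baseline. A gene's planted category follows from its multipliers
by the same priority order as the classifier (`planted_category`).

**Migration movies.** Cells perform a persistent random walk (constant
step = speed × frame interval, heading diffusion sd 0.35 rad/frame) and
switch speed at the stimulation frame. Nuclei exclude each other
(pairs closer than 3 nucleus-sigmas are pushed apart symmetrically) and
reflect at field borders — both choices keep step lengths meaningful
and nuclei separable, as in a real monolayer at sub-confluent density.
Ground-truth speeds are recomputed from the final true coordinates, so
collision adjustments are folded into the truth. Default 10-min frames
(the assay range is 10–14 min), 0.64 μm/px.

**Pillar movies.** Undeflected positions form a hexagonal lattice
(default 4 μm pitch); the field size is chosen to hold roughly the
requested pillar count. Pillars under an elliptical cell footprint
follow a stationary 2-D Ornstein–Uhlenbeck process (exact
discretization x_{t+1} = φx_t + σ√(1−φ²)ε, φ = e^(−Δt/τ)), the natural
stationary, exponentially-autocorrelated model — exactly the structure
the half-time analysis assumes. Pillar tops are soft-edged discs
(radial error-function profile, 2 μm diameter, 0.3 μm edge blur at
0.2 μm/px), radially symmetric so centroid localization is unbiased.
Per-pillar-frame drop-outs emulate detection misses. The actin channel
is a static soft ellipse re-noised per frame.

The localization-precision fixture
(`generate_pillar_localization_set`) uses 8 μm spacing rather than the
array's 4 μm pitch: with test deflections up to 1.5 μm, neighbouring
disc tails would otherwise enter the centroid window and the measured
error would reflect blob overlap, not localization precision (which is
what the ~2 nN claim is about). Real-array analyses keep 4 μm.

What passing tests on these data do **not** show: robustness to uneven
illumination, debris, cell division/death, focal drift, or non-Gaussian
adhesion profiles. Those require real images.

## FA segmentation

Per channel: Gaussian filter (σ = 1 px) → rolling-ball background
subtraction (radius 10 px; the original macro's radius is unrecorded,
10 px ≈ 3 μm comfortably exceeds adhesion scale) → watershed partition
of the image into catchment basins seeded at h-maxima (h = 10% of the
background-subtracted dynamic range) → Otsu threshold computed
*within each basin* (so dim and bright adhesions are thresholded at
their own level — the "watershed-masked clustering" structure) →
8-connected labels. The minimum-size filter (4 px) counts
above-threshold pixels in the **unsmoothed** background-subtracted
image: pre-filter blurring inflates every object's thresholded
support, and counting raw pixels prevents sub-4-px debris from being
promoted past the filter. A global gate (max > median + 6 robust SDs)
returns an empty mask for blank frames.

Nuclei: Gaussian blur, Otsu threshold, and a watershed on the smoothed
intensity seeded at intensity maxima. Intensity seeding (rather than
the distance transform) splits touching nuclei whose centres are still
distinct, because the intensity saddle between two nuclei is far deeper
than the distance-transform saddle.

Moment features, with λ₁ ≥ λ₂ the eigenvalues of the per-pixel
coordinate covariance of a label: elongation = 1 − λ₂/λ₁ (0 for a
disc), extension = λ₁/area, dispersion = 4π(λ₁+λ₂)/area, orientation =
principal-axis angle from the +x (column) axis in [−90°, 90°),
compact factor = 4π·area/perimeter² (Crofton perimeter; capped at 1.1
to absorb discretization overshoot). The feature *names* follow the
field's convention; exact formulas in the original tooling are not
public, so these definitions are the package's own and are stated here
so results remain interpretable.

## Screen statistics

The signed two-sample KS statistic evaluates F_ref − F_test at every
sample point (right-continuous ECDFs) and reports the value at the
argmax of the absolute difference; when several points tie (within
1e-12, absorbing k/n float rounding) the earliest point wins. Positive
values mean the test sample is shifted to larger adhesions. The
p-value uses the asymptotic Kolmogorov distribution at λ = √(nm/(n+m))·D,
evaluated directly in log10: the alternating series
Q(λ) = 2Σ(−1)^{k−1}e^{−2k²λ²} with the leading term factored out for
λ ≥ 0.75, the theta-dual series below. This keeps p-values like 10⁻²⁷⁷
(routine at screen scale) exactly representable.

Hit categories are assigned in priority order: increase (stringent cut
on DMSO-vs-control), decrease, assembly-blocked (no significant change
nocodazole-vs-own-DMSO), disassembly-blocked (significant nocodazole
increase and no significant change washout-vs-nocodazole), none.
"No significant change" is |D| < 0.05 **or** log10 p > −10; the
original analysis combined thresholds with visual inspection and never
quantified this, so the defaults are package conventions, exposed in
`HitThresholds` and echoed in every run manifest. Deselected genes
(manual curation) keep their category but leave the hit total. Hit
calling uses vinculin-channel records; paxillin is carried as a
parallel output.

No multiple-testing correction is applied across genes — the stringent
fixed thresholds play that role by design.

## Migration

Overlap tracking links each label to the previous-frame label sharing
the most pixels, greedily by overlap size (ties by centroid distance),
one-to-one; unmatched labels start new tracks and a missed link ends a
track (no gap closing — identity continuity is the point of overlap
tracking). Speeds are mean per-step displacement over the frame
interval, split at the stimulation frame (a step belongs to the phase
of its end frame); tracks shorter than 5 steps per phase are dropped.
Dunn's post test uses the rank-based z statistic with tie correction
and Bonferroni adjustment over all pairs, matching common
post-Kruskal–Wallis practice. The all-three-tests normality rule uses
Lilliefors (KS with estimated parameters — the appropriate form when
μ, σ come from the data), d'Agostino–Pearson, and Shapiro–Wilk, all at
α = 0.05.

## Traction forces

Mechanics: Euler–Bernoulli tip-loaded cantilever k = 3πEr⁴/(4h³)
(shear and substrate-warping corrections are not applied; the
production stiffness k = 65.8 nN/μm is taken as an input for force
conversion, and back-solving gives an elastomer modulus of ~1.93 MPa).
The continuum-equivalent substrate rigidity is E_eff = 9k/(4πr), the
sphere-indentation equivalence for micropost arrays; with the printed
k it evaluates to 47.1 kPa (the printed 47.2 kPa differs only by
rounding).

Localization: difference-of-Gaussians band-pass, local maxima above
median + 5 robust SDs, then three iterations of an intensity-weighted
centroid in a circular window re-centred on the running estimate. The
re-centring removes the window-truncation bias of a single-pass
centroid; measured precision on the synthetic fixture is ~8 nm
(≈ 0.5 nN), comfortably within the ~2 nN design precision.

Reference grid: lattice orientation is estimated from
nearest-neighbour vectors folded onto the 60° hexagonal sector
(angles ×6, circular mean), pitch from their median length; origin and
basis are then refined by trimmed linear least squares on integer
lattice assignments (residuals above 20% of the pitch are dropped each
round, 4 rounds). Only pillars outside the cell mask inform the fit,
falling back to all pillars with a warning when fewer than 10 are free.
Deflections beyond half the pitch flag lattice mis-assignment and are
excluded.

Tracking: greedy nearest-neighbour linking gated at 2 μm (half the
pitch), with unmatched tracks retried one frame later (2-frame gap
closing). Full optimal assignment is unnecessary at 4 μm pitch with a
2 μm gate — candidate sets rarely overlap.

Cell mask: Gaussian low-pass, median background subtraction, then two
edge maps (Sobel and Laplacian-of-Gaussian), each thresholded at
max(Otsu, median + 8 robust SDs) — edge pixels are a small minority,
which defeats plain Otsu — dilated and hole-filled; the union is eroded
by the same element so the footprint hugs the cell outline, and small
components are removed.

Selection: cell-coupled = inside the mask in ≥ 50% of frames; coupled
pillars are ranked by time-averaged deflection magnitude and the top
5% (at least one) kept. Ranking by time average, not per-frame maxima,
keeps the selection noise-robust.

Autocorrelation and half-time: per-pillar force-magnitude series are
mean-subtracted and their sample autocorrelation normalized to 1 at
lag 0 using the (n−lag) denominator; curves are averaged across
pillars (and per cell first when cell identities are given), then
a·e^(−λt)+c is least-squares fitted over lags 0…120 min (25 points at
5-min frames) and the half-time is ln 2/λ. Two numerical choices
deserve emphasis, because the naive estimator is badly biased at this
series length (80 frames, τ ≈ 30–40 min): the divide-by-n
autocorrelation tapers the curve by (1 − lag/n), and per-series mean
removal depresses all lags by roughly Var(sample mean)/Var(series)
≈ 2τ/(n·Δt). A no-offset exponential fit absorbs both into λ and
halves the recovered half-time. The (n−lag) normalization removes the
taper and the free offset absorbs the mean-removal depression;
with them the fitted half-time recovers the closed-form OU value
within ~20% at these series lengths, and pipeline-vs-ground-truth
agreement (same estimator on true deflections) is within a few
percent. The residual low bias is intrinsic to short-series
autocorrelation estimation and is why accuracy claims are stated
against the truth-series oracle, not the asymptotic closed form.

Condition comparisons: extra-sum-of-squares F-test between the shared
(a, λ, c) fit of both averaged curves and the separate fits
(Δdf = 3); Welch's unequal-variance t-test on per-pillar mean forces.
Under iid Gaussian curve noise the F-test's measured type-I error at
α = 0.05 is ~0.05–0.07 over 200 null replicates.

## Problem sizes used in tests

Test and acceptance workloads are scaled for a laptop-class single
core: FA recall uses one 512² field (8 cells, ~200 adhesions); the
planted screen uses 20 genes × 3 conditions × duplicate wells at
~1600 ground-truth adhesions per condition; migration uses 30–50 cells
over 20–60 frames at 512²; the tracking/half-time movie uses ~390
pillars × 80 frames at 0.2 μm/px; localization precision uses 200
single-frame images (25 pillars each). The complete suite runs in
about two minutes.

## Known limitations

- Segmented adhesion areas are systematically inflated by the Gaussian
  pre-filter; the screen statistics are shift-based and unaffected,
  but absolute areas should not be compared across different
  `SegmentationParams`.
- The half-time estimator retains a modest low bias at 80-frame series
  (see above); comparisons *between* conditions analysed identically
  are unaffected.
- The overlap tracker has no division/death handling; dividing cells
  simply end one track and start two.
- The F-test on averaged autocorrelation curves treats curve residuals
  as independent, which finite-series autocorrelation estimates only
  approximate; the measured null calibration is acceptable but slightly
  liberal.
- The synthetic generators make no attempt at photorealism (uniform
  illumination, symmetric PSF-free spots, stationary OU forces).
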