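# Methods

## Scope and model

The package quantifies the spatial relationship of two fluorescence
channels on a common 3-D voxel grid, the nuclear partition of a tagged
protein, and immunoblot band content, with replicate statistics that
respect the subject/cell hierarchy.  All algorithms are validated
against synthetic scenes with known ground truth; the generator is a
first-class, tested module, not a fixture.

## Conventions

Arrays are stored in TIFF page order `(z, y, x)`; physical triples
(voxel size, displacements, shifts) are `(x, y, z)` in nanometres.
Coordinates are voxel-centred and 0-based: position = index × voxel
size.  Default geometry follows oversampled confocal acquisition of
skeletal muscle: 60 nm x-y pixels, 120 nm z steps, and a point-spread
function of 350 nm lateral / 480 nm axial FWHM, modeled as a separable
3-D Gaussian with σ = FWHM / (2√(2 ln 2)).

## Synthetic scenes

**Punctate two-channel stacks.** Puncta are delta impulses deposited
with trilinear weights, then convolved with the Gaussian PSF, so total
photon mass equals the sum of punctum amplitudes (placement keeps a
4σ + displacement margin from the grid edge; truncation is below
0.1%).  Amplitudes are log-normal with σ_log = 0.3, emulating
heterogeneous staining — the regime Li's sign-based quotient was
designed for.  Channel B repeats channel A's positions for a chosen
colocalized fraction; a displacement vector and/or isotropic Gaussian
dispersal applies to all B puncta or only to the non-colocalized
complement (mode flag).  Noise is Poisson on (signal + background)
plus Gaussian read noise — the standard photon-counting model.
Defaults: 256×256×20 voxels, 150 puncta, peak ≈ 200 photons,
background 10 counts, read noise 2 counts.  Identical parameters and
seed give bit-identical output.  Dispersal jitter may push an
occasional punctum off-grid; that mass is lost from the field, which
is physical and negligible for the statistics.

**Nuclear scenes.** Axis-aligned ellipsoidal nuclei (default
semi-axes 1500 × 1200 × 800 nm, sized so several nuclei fit a
desk-scale stack while keeping the boundary-voxel shell a small
fraction of nuclear volume) are placed by rejection sampling with a
scaled-distance criterion (> 2.4) that guarantees non-overlap and
leaves a resolvable gap; the whole configuration restarts when greedy
placement gets stuck, and fails after a bounded number of restarts.  A
stated fraction f of total signal mass is spread uniformly over
nuclear voxels, the remainder uniformly outside, so the
nuclear/cytosolic density ratio has the closed form
(f / V_nuc) / ((1−f) / V_cyt).  PSF blur is **off** by default here:
the quantity under test is a region-density ratio, and blur moves mass
across the region boundary, detaching the scene from its closed form.
An opt-in flag applies the blur for qualitative work.

**Lane images.** The axial profile is a sum of area-parameterized
Gaussians plus a linear baseline, replicated across the lane width
with i.i.d. Gaussian pixel noise.  Because analysis reduces the lane
by the mean across its width, profile-level noise is pixel noise
divided by √width.

What the generator does *not* emulate: sarcomere banding, membrane
geometry, spectral bleed-through, optical aberrations, blot smile or
saturation.  Passing tests therefore demonstrate correctness of the
estimators under the stated statistical model, not robustness to every
artifact of real specimens.

## Colocalization measures

Background per channel defaults to the 1st-percentile intensity of the
stack; subtraction keeps negative residuals (no clipping), which
leaves Pearson R exactly invariant under affine gain.  Pearson R is
undefined for a constant channel and returned as NaN with a flag.

The ICQ is computed as (pixels with strictly positive covariance) /
(all masked pixels) − 0.5.  The printed sign-sum form of the quotient
would reach −1.5 at perfect exclusion, contradicting its stated
[−0.5, 0.5] range; the positive-fraction form reproduces both
endpoints (+0.5 identity, −0.5 inversion) and is the one implemented.
Zero-covariance pixels count in the denominator only.

Van Steensel profiles use integer-pixel shifts (no interpolation; the
measured plot is the discrete object), correlation over the overlap of
the mask with the shifted domain, no wrap-around, and shifts whose
overlap falls under 20 masked pixels are dropped.  A Gaussian plus
constant offset is fitted by Levenberg-Marquardt with bounded
parameters; sub-pixel shift resolution comes from the fitted centre.
Fit acceptance: R² ≥ 0.7 and |centre| within the scanned range.  On
rejection the reported shift is the measured argmax and the FWHM the
interpolated full width at half of (max − min).  The default scan is
±20 px (±1.2 µm laterally), enough to cover the half-width of the
broadest profiles of interest (≈1.8 µm FWHM).  The VS shift is
reported as a magnitude.  Whether to correlate raw or
background-subtracted intensities is configurable; subtracted is the
default.  The analysis mask is mandatory in concept with a full-frame
default.

## Localization

Nuclei are segmented from the marker channel by a 200 nm Gaussian
blur, a global Otsu threshold, hole filling and removal of components
below 2 µm³; touching nuclei may merge (component count is not
guaranteed).  Region densities are means of background-subtracted
signal per voxel; "area" is voxel count since analysis runs on full
3-D stacks.  The background may be a calibrated scalar (detector
pedestal) — preferable when signal fills the whole frame, where an
in-image percentile would swallow real density.  The ratio is exactly
gain-invariant and the two orientations are exact reciprocals.

## Densitometry

Single-band mass: baseline through the means of two 5-px flanking
margins; mass = Σ max(intensity − baseline, 0) in the window (clipped,
because the quantity is signal *above* background).  Lane
normalization: mean above-background intensity over ≥ 50 px of the
source-gel lane; non-positive factors are an error (blank lane).

Dual bands: least squares of two Gaussians + linear baseline, second
centre parameterized as first + separation with separation ≥ 1 px.
The SSE surface of overlapping-band decompositions is flat and
multi-modal, so the fit starts from several moment-based seeds (peak
pair if two local maxima exist; symmetric and asymmetric splits about
the above-baseline centroid otherwise) and keeps the best.  Band
widths are free by default; a shared-width option exists for doublets
known to be the same species (e.g. a protease and its autolyzed form
in one lane), where it sharply reduces the variance of the mass ratio.
Clipping applies to band_mass only, never inside the fit.  Failures
are flagged, never silently patched: non-convergence, non-positive or
negligible (< 1% of total) mass, separation pinned at a bound, or an
extra-sum-of-squares F test (α = 0.05) finding no support for a second
band over a single-Gaussian fit — the signature of a one-band profile.

## Statistics

Hierarchical summaries are two-stage: subject means first, grand mean
= unweighted mean of subject means, SEM = SD of subject means / √N;
the median is reported beside every average.  Group tests run on
subject means, never pooled cells — the standard correction for
pseudoreplication; Shapiro and Levene checks (α = 0.05) select t vs.
Mann-Whitney unless overridden, and identical samples return p = 1 by
convention.  Percent differences of medians are rounded to integers
for reporting.  The p of no correlation is the two-tailed t transform
t = R√((n−2)/(1−R²)) with n−2 df.  Two-sample power uses the
noncentral-t with noncentrality (Δ/sd)√(n/2); sidedness is an explicit
argument because the two conventions differ materially near common
design points (≈0.74 two-sided vs ≈0.84 one-sided at Δ/sd = 30/27,
n = 12/group), and neither is asserted as canonical.

## Pipeline

Per-scene seeds derive from `SeedSequence([master, group, subject,
cell])`, giving bit-identical bundles under a fixed master seed with
independent scenes.  Cell-level failures become flags in the output
table; the batch continues.  Outputs: per-cell CSV (+ JSON twin at
full precision) with group summary rows reporting N and n separately,
pairwise group comparisons, and a ground-truth recovery report in
simulate mode.

## Problem sizes and tolerances

Test and validation runs use desk-scale scenes — 64–160 px laterally,
16 z-slices, 25–40 puncta, 10–20 seeds for recovery suites, 200–500
replicates for Monte-Carlo calibration — chosen so the full suite runs
in well under a minute of CPU per module while keeping Monte-Carlo
error comfortably inside the asserted tolerances.  Oracle-equivalence
checks (vectorized vs. brute-force loop implementations of R and ICQ)
assert agreement to 1e−12; recovery checks assert the tolerances
motivated by the geometry (e.g. VS shift within half a lateral voxel
of a 120 nm truth).

## Known limitations

- Sub-voxel displacements below ~half a pixel are not resolvable by
  integer-shift correlation profiles; the Gaussian-fit centre
  interpolates but inherits profile noise.
- Free-width dual-band decomposition at 1.5σ separation is
  statistically ill-conditioned; per-lane ratios scatter ~±25% at
  pixel SNR 20 even though the estimator is unbiased.  Use the
  shared-width option when bands are a same-species doublet.
- Otsu-based nuclear segmentation dilates boundaries by a fraction of
  the blur width; density ratios from segmented masks carry a few
  percent bias relative to the generating regions, growing as nuclei
  shrink toward the blur scale.
- The hierarchical estimator is the unweighted means-of-means form; it
  does not model unbalanced designs or within-subject correlation
  structure the way a full mixed model would.
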