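# Methods

This note documents the models, conventions and numerical choices behind
granulequant, in the order data flows through the package.

## The measurement problem

Knockdown experiments in cultured neurons change where a protein sits:
depleting NCDN changes the number, size and brightness of cytoplasmic FUS
granules; depleting FUS lowers the cytosolic level of NCDN. Both readouts
are fluorescence intensities in 3D confocal stacks acquired over several
experimental weeks with week-to-week gain drift, so every statistic has to
be (a) computed per image, (b) normalized within its week against
non-targeting controls, and (c) compared across conditions with methods
that do not assume normality. The package implements that chain, and a
synthetic-data generator that plants known effects so the chain can be
validated end to end.

## Synthetic stacks (`simulate`)

Each simulated acquisition has two channels on a common voxel grid,
default 16 × 256 × 256 voxels at 0.45 µm (z) × 0.1 µm (x, y) — the axial
step of a 63× oil-immersion z-stack acquisition.

**Geometry.** `n_nuclei` (default 4) ellipsoidal nuclei with in-plane
semi-axes drawn from 2.4–3.2 µm and axial semi-axes 1.6–2.2 µm, placed by
rejection sampling so somata do not overlap. Each soma is a concentric
ellipsoid 1.7× the nucleus radius; three random-walk tubes of radius
0.35 µm emulate neurites. Cytosol = (soma ∪ neurites) − nucleus.

**DAPI channel.** A smooth quadratic-falloff profile inside each nucleus
(peak 500 counts) over a 5-count background.

**Target channel.** A diffuse cytosolic compartment (40 counts), an
optional diffuse nuclear compartment, and granules rendered as 3D Gaussian
blobs. Granule count is Poisson with mean *density × cytosol volume*
(default 0.12 µm⁻³); centers are uniform over the cytosol; half-widths are
log-normal (median 0.10 µm, log-SD 0.2) and are combined in quadrature
with a confocal PSF term (0.35 µm axial, 0.08 µm lateral), which is what
makes rendered blobs axially elongated, as in real data, and keeps the
voxel-sampled peak intensity stable under sub-voxel z offsets. Peak
amplitudes are gamma(shape 20, scale 150), i.e. ≈ 3000 ± 670 counts —
bright, tightly distributed puncta well below the 30,000-count saturation
filter. Diffuse compartments are smoothed within their own support so
that only granules carry high spatial frequencies but the ground-truth
masks remain exact.

**Noise.** Poisson shot noise on the expected counts (gain 1; gain 0
disables it and reproduces the noiseless render bit-exactly), then
additive Gaussian read noise (SD 3 counts). Ground truth (granule table,
masks, noiseless render) is recorded before noise.

**Conditions and batches.** Per-condition multipliers act on granule
density, size, amplitude and cytosolic baseline. Batches ("weeks") carry a
multiplicative log-normal gain jitter (log-SD 0.1), making per-batch
normalization non-trivial. All randomness descends from one integer seed
through `numpy` seed sequences; identical parameters and seed give
bit-identical stacks.

**Two scenario presets.** `SimulationParams()` (equivalently
`fus_scenario()`) is the granule-rich channel used for spot detection;
`ncdn_scenario()` is the diffuse-signal channel used for the cytosolic
analysis — sparse, modest puncta (mean amplitude 100 counts), an
NCDN-level nuclear compartment (40 counts, so subtracting the nucleus
matters), and a 2-count camera offset so the cytosolic median tracks the
planted effect with little additive bias.

**What the generator does not emulate:** dendritic-spine morphology, a
real optical PSF (blobs are Gaussian by construction), depth-dependent
attenuation, autofluorescence, or camera-specific noise calibration.
Passing tests demonstrate that the pipeline recovers known effects under
this idealized but structurally faithful model; they do not certify
performance on real acquisitions with artifacts outside the model.

## Segmentation (`segmentation`)

The triangle (Zack) threshold builds a 256-bin histogram over the observed
min–max range, draws the chord from the histogram peak to the farthest
non-empty tail bin, and returns the bin-center intensity maximizing the
perpendicular distance between histogram and chord; binarization is
`value > t`. Constant images raise a dedicated degenerate-histogram error
that batch pipelines log per image rather than crash on.

Nucleus pipeline: DAPI MIP → triangle threshold → remove 8-connected
objects with area < 20 px (strictly smaller; 20-px objects stay) → fill
holes → one dilation with a 3×3 square element → relabel. The mask is 2D
and broadcast across z.

Foreground pipeline: 3D Gaussian smoothing at σ = 0.5 voxel → per-slice
triangle threshold (a global-threshold mode exists behind a config switch)
→ per-slice removal of objects < 30 px. Degenerate slices contribute empty
foreground with a log entry. The cytosolic statistic is the median of the
*raw* channel over foreground-minus-nucleus voxels.

Connectivity is 8-connected in 2D and 26-connected in 3D throughout.

## Spot detection (`spots`)

Auto-contrast clips to [mean − k_low·SD, mean + k_high·SD] and rescales to
[0, 1]; defaults k = (1, 12). The detector smooths at σ = 1 voxel,
computes the scale-normalized negative Laplacian of Gaussian
−s²∇²G_s at scale s (default 1.0, accepted range 0.75–1), and keeps
voxels with response > cutoff (default 0.045, accepted range
0.015–0.045). Scale and cutoff are deliberately exposed as the per-batch
tuning pair. 26-connected clusters record voxel count ("area" in pixel
units — a documented convention for a 3D segmentation), the maximum *raw*
intensity (so the photon-count filter keeps physical meaning), centroid,
projected (y, x) footprint area, and physical volume. Quality filters
remove clusters with area < 5 or > 300 voxels or maximum intensity
> 30,000 counts; boundary values are kept (the removals are strict
inequalities). In practice the saturation filter is also what removes
detections belonging to a saturated bright nuclear compartment.

The default auto-contrast and cutoff were chosen together with the
generator's amplitude law so that the dimmest granules stay above cutoff
while knockdown-enlarged (×1.5) granules stay under the 300-voxel cap;
the trade-off is real and documented here because any user retuning one
side should expect to retune the other, exactly as per-week parameter
adjustment works on real data.

## Statistics (`stats`)

**Skew-normal peak.** Per-image cluster maximum intensities are fitted by
maximum likelihood to the 3-parameter skew-normal SN(ξ, ω, α) (fit on raw
values, not binned counts; a histogram-based fit would discard
information and add a bin-width choice). The per-image summary is the
mode of the fitted density, located by bounded scalar minimization on a
bracket that provably contains it (between ξ and the mean direction); a
dense grid search is the test oracle. Fits need n ≥ 10 and non-zero
variance; a failed optimization falls back to the normal-fit moments with
`converged=False`.

**Normalization.** For each batch, the normalizer is the peak of a
skew-normal fitted to the *pooled* control clusters of that batch; every
image's peak is divided by it. This is scale-equivariant (multiplying a
batch by c changes nothing) and makes weeks comparable.

**Outliers.** One pass: remove x with |x − mean| > k·SD, k = 2, using the
sample (n−1) SD computed once on the full set. With fewer than 3 values
the rule is skipped with a warning.

**Bootstrap.** Each group is resampled with replacement at its own size,
B = 10,000 times; the difference statistic (median by default) is recorded
per iteration; CI = 2.5/97.5 percentiles; two-sided
p = 2·min(#{d ≤ 0}, #{d ≥ 0})/B, floored at 1/B and capped at 1. Fixed
seeds give bit-identical results. A calibration caveat worth knowing: the
percentile CI of a *median* difference at n = 20 per group covers the null
≈ 96.5–97% of the time rather than 95%, because the bootstrap distribution
of a median at small n is supported on order statistics and is therefore
discrete; the smooth mean statistic covers ≈ 94%. Both numbers are
reported by the acceptance script; the discreteness bias is a property of
the estimator, not of the implementation.

**ANOVA.** One-way ANOVA (scipy `f_oneway`) with Tukey HSD adjusted
pairwise p-values (scipy `tukey_hsd`); all-identical input is short-
circuited to F = 0, p = 1.

## Morphometry (`morphometry`)

Cell-body ROIs are 2D masks, stored as exact run-length encodings in
JSON; for synthetic data the generator's soma label map supplies them. A
cluster belongs to a cell when its (y, x) centroid lies inside the ROI and
outside every nucleus footprint — centroid membership is a package
convention chosen for determinism, since sub-voxel partial-overlap rules
add complexity without a defensible ground truth. The minimum detectable
size (default 0.01 µm) is interpreted as the equivalent spherical diameter
(6V/π)^(1/3). Per-cell outputs are granule count, mean projected area
(µm²) and mean volume (µm³); group comparisons warn below 16 cells per
condition.

## Pipelines (`pipeline`, `cli`)

`run_ncdn_analysis`: segmentation → per-image cytosolic medians →
per-batch division by the median of control medians → per-condition
outlier removal → bootstrapped difference of medians per knockdown versus
control. `run_fus_analysis`: detection → filters → per-image skew-normal
peaks (images with < 10 clusters are excluded from fits, logged) →
per-batch control-peak normalization → outliers → bootstrap; optional
per-cell morphometry with ANOVA/Tukey when ROIs are supplied. Per-image
failures exclude the image with a log entry; a batch without controls
aborts. Reports carry a config hash and seed, and rerunning with the same
inputs reproduces every number exactly.

## Mosaicism (`mosaicism`)

VAF = alt/total with a Wilson score interval (chosen over Wald for its
small-count behavior). Carrier cell fraction = 2·VAF capped at 1 under
the heterozygous assumption; a VAF above 0.5 warns. Note that a 24.5%
VAF converts to 49% of cells under this standard formula; published
figures derived from the same counts sometimes use unstated corrections
(e.g. ~39%), and this module deliberately implements only the standard
conversion rather than guessing one.

## Problem sizes used in validation

The test suite and acceptance script run entirely on simulated data at
sizes chosen to exercise every code path with stable statistics:
20 full-size stacks for detection F1 (pooled match = ground-truth center
inside a kept cluster), n = 10,000 draws for skew-normal recovery, 500
null simulations at n = 20 per group for bootstrap coverage, and knockdown
experiments of 6–8 images per condition per batch over 2 batches. These
are the package's own validation conditions; larger runs only narrow the
confidence intervals.
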