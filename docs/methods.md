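# Methods

`pamoct` quantifies dual-modality fundus images: photoacoustic microscopy
(PAM, optical-absorption contrast at 532 nm and 1064 nm) and optical
coherence tomography (OCT, backscattering contrast at 840 nm). The package
has two halves: a forward simulator that generates eye-like phantom volumes
with known ground truth, and the analysis chain (en face reconstruction,
vessel extraction, metric computation) that is the actual subject of the
package. Every analysis claim the test suite makes is a recovery statement
on simulated scenes; this note records the models, the defaults, and what
the tests do and do not establish.

## Forward model (phantom)

The simulator is a projection/attenuation toy model, not a wave solver.
Each voxel carries per-structure optical coefficients (dimensionless,
wavelength-tagged), and

* PAM amplitude = (pulse energy / 90 nJ) x absorption x exp(-z/L) x
  lateral sensitivity ramp + additive zero-mean Gaussian noise
  (`noise_sigma_pam`, default 0.02 amplitude units);
* OCT amplitude = backscattering x exp(-z/L) x multiplicative Rayleigh
  speckle of unit mean (`speckle_shape` scales the variance).

Beer–Lambert depth attenuation uses per-modality effective lengths
(`ATTENUATION_LENGTH`, voxels): 45 for 532 nm (visible light is absorbed
within the retina, so sub-RPE structure vanishes), 600 for 1064/840 nm.
The lateral ramp falls linearly from 1.0 on the transducer side to
1 − `lateral_falloff` (default 0.6) on the far side, emulating a one-sided
unfocused needle transducer. An optional detector saturation level clips
PAM amplitudes; the pipeline enables it (level 2.0) for lesion scenes so the
laser-damage core renders as a uniform white patch — that is what makes a
saturation threshold a meaningful lesion detector.

Scenes hold a branching vessel tree (capsule segments with radius 1.5–2.5 px
grown by a seeded random walk; retinal layer at 0.3 nz, choroidal at
0.62 nz), an RPE band (6 voxels at 0.5 nz; dominant NIR absorber, brightest
OCT scatterer), a scattering retina slab, and optionally a CNV-like lesion:
a strongly absorbing core protruding into the subretinal space plus a
perilesional ring of neovessels just above the RPE. Default grids are
64 x 64 x 256 — a 4x lateral / 8x axial scale-down of a realistic
256 x 256 x 2048 acquisition — chosen so the full suite and the acceptance
script run in seconds while leaving vessels 3–5 px wide, the regime the
filter defaults target.

The contrast agent model is a piecewise blood-pool curve: the multiplier is
1 at t = 0, rises linearly to 1 + gain x concentration at `t_peak`
(default 2 min), then decays exponentially (`tau_decay` = 15 min) toward
`floor_factor` = 0.9 < 1, so the 60-minute point falls below baseline (the
empirically observed late decline; the sub-baseline floor stands in for
slow optical degradation of the exposed eye). Absorption gain 1.15 per
(mg/mL) reproduces an approximately 2.1-fold peak vascular PAM enhancement
at 1 mg/mL; scattering gain 0.083 gives the much weaker OCT response. After
injection a fraction (0.3) of the vascular gain leaks into the RPE band
(extravasation), which is why whole-field means still decay below baseline
at 60 min. Tube phantoms use separate calibration gains (0.446 absorption,
2.5 scattering per mg/mL) so that simulated tube measurements land at
~144.6 % of saline (PAM, 1 mg/mL) and ~3.5-fold (OCT).

## Reconstruction

Volumes are indexed (fast axis x, slow axis y, depth z), zero-based
everywhere; a slice colloquially called the "N-th" B-scan is index N−1.
PAM en face images are maximum amplitude projections over depth; OCT en
face images are depth sums; both are overridable. Normalization is min–max
to [0, 1] with the convention that a constant image maps to all zeros
(keeps downstream thresholding well defined). Contours are marching-squares
iso-lines at n equally spaced levels strictly inside the image range; a
constant image yields no contours. Acquisition time is n_bscans/frame_rate,
reported to the nearest second (256 at 19.5 frames/s → 13 s).

## Vessel extraction

The binarization chain is: Gaussian pre-smoothing (sigma 0.8 px, the
denoising step) → fast-axis flat-field correction → multiscale Hessian
vesselness → adaptive hysteresis threshold → morphological cleaning →
Zhang–Suen thinning.

Flat-field: the dominant shading is the 1D transducer ramp, so the gain is
estimated per fast-axis row as the 30th percentile over the slow axis
(robust to the bright, sparse vessels), smoothed (sigma 16 px), and divided
out. Without it, far-side vessels sit below any global-range threshold and
the mask loses up to ~40 % of the far half.

Vesselness: per scale sigma, the image is convolved with Gaussian-derivative
kernels to get the Hessian; eigenvalues |l1| <= |l2| give blobness
R_b = |l1|/|l2| and structureness S = sqrt(l1^2 + l2^2), and the response is
exp(−R_b²/2β²)(1 − exp(−S²/2c²)) where the wrong-sign l2 (polarity) zeroes
the pixel. Defaults: scales {1.5, 2, 3} px (matched to 3–5 px vessel
widths at the 64-px grid scale; the 1 px scale is omitted because it chiefly
amplifies pixel noise), β = 0.5, c = half the maximum Frobenius norm per
scale. Derivatives are normalized by sigma^1.5 (the ridge-detection
gamma = 3/4 choice), for which the response of a Gaussian-profile ridge of
width sigma_true peaks exactly at scale sigma_true; with sigma² weighting
the peak sits at sqrt(2) sigma_true and discrete scale selection picks the
wrong scale. Note that with the auto-c rule the on-centerline response is
1 − e⁻² at every scale, so scale-selection experiments must fix c.

Threshold: foreground requires value > local Gaussian mean (15 px window) +
offset x global range. A single offset either clips vessel edges (large
offset) or admits noise (small offset); the default is therefore a
hysteresis pair — the 0.08-offset mask seeds a 3-step 8-connected
conditional dilation restricted to the 0.025-offset mask — which recovers
full vessel width while isolated low-contrast pixels stay out. Cleaning
closes with a 5 x 5 square (a Chebyshev disk; a cross-shaped Euclidean
disk(1) cannot bridge 1 px gaps between 1 px lines) and drops 8-connected
components under 10 px. Thinning is the two-subiteration Zhang–Suen scheme
(`skimage.morphology.skeletonize`, method "zhang"): idempotent,
topology-preserving, deterministic; line ends erode by roughly half the
local width, the usual parallel-thinning end effect.

## Metrics

* VAD = vessel-mask pixels / total pixels; VSD = skeleton pixels / total
  pixels (total-area normalization). Since the skeleton is one pixel wide,
  VSD tracks total vessel length.
* VCI = P²/(4 pi A). The perimeter P is the weighted boundary-configuration
  estimate (`skimage.measure.perimeter`, 4-neighborhood). The convention
  matters: a raw exposed-edge count gives 8r for a digital disk and inflates
  a disk's VCI to ~1.6, whereas the weighted estimate keeps it within ~8 %
  of the ideal 1.0. On an axis-aligned 40 x 5 rectangle the estimate is ~86
  versus the ideal 2(L+W) = 90, so closed-form cross-checks carry ~10 %
  convention slack.
* Lesion area: threshold at 0.98 of the dynamic range, keep the largest
  8-connected component, fill holes; valid only on images where the lesion
  is saturated/clipped (PAM with the detector clip). The speckled OCT
  depth-sum has no clipping mechanism, so the four-way lesion-area agreement
  is checked across the four PAM products (VIS/NIR x pre/post injection);
  the OCT entry is still recorded.
* SNR = 20 log10(mean(signal)/std(background)) in dB, masks disjoint.
* Enhancement: `fold` = 100 post/pre and `increase` = 100 (post−pre)/pre are
  both computed and must be labeled; they differ by exactly 100 points.

## What the tests show — and do not

All recovery statements are against this generator. The phantoms emulate
layered geometry, modality contrast, depth attenuation, lateral falloff,
speckle/additive noise, agent kinetics, and detector saturation; they do not
emulate eye motion, pulse-to-pulse energy jitter, refractive blur,
heartbeat/breathing artifacts, or real vessel tortuosity statistics, so a
passing suite demonstrates internal consistency of the algorithms, not
clinical-grade segmentation. No physical optical coefficients enter the
simulator; its constants are free parameters, which makes every recovery
test a self-consistency test rather than a physical calibration.

Measured behavior of the default extraction on 30 random noise-free scenes:
most recover VAD within a few percent, but roughly a quarter of scenes —
the densest trees, where capsule unions and junction responses interact —
exceed 10 % relative VAD error (worst ~20 %, always toward
under-segmentation); Dice stays above ~0.75 throughout and above 0.85 on
typical scenes. The five canonical test seeds recover VAD within ±10 % with
skeleton-to-centerline distances below 1 px. With additive image noise up
to sigma 0.1 the default parameters keep Dice >= 0.7.

## Numerical conventions

Min–max normalization maps constant images to zero. Vesselness at |l2| = 0
is zero (no division). The empty vessel tree rasterizes to an all-false
mask with a warning; empty masks make VCI and SNR raise undefined-metric
errors rather than return sentinels. All randomness flows through
`numpy.random.default_rng(seed)`; identical (config, seed) pairs produce
bit-identical volumes, maps, and manifest checksums. Thinning ties need no
tie-break because deletions within a subiteration are evaluated
simultaneously on the whole frame.
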