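# Methods

## Problem and model

Multicenter brain FDG-PET studies mix images from scanners with
different effective spatial resolution. When phantom calibration scans
are unavailable (the usual retrospective situation), the
scanner-specific smoothing filter that equalizes resolution must be
estimated from the subject images themselves.

`petharm` models each scanner's point-spread function as a separable
3D Gaussian described by two FWHM values in mm: one shared by the two
transaxial axes (XY) and one axial (Z). Sequential Gaussian blurs
combine in quadrature,

    FWHM_total^2 = FWHM_a^2 + FWHM_b^2,

so the filter required to bring a scanner of intrinsic resolution
`FWHM_scanner` to a coarser common target is
`sqrt(FWHM_target^2 - FWHM_scanner^2)` per direction, clamped to zero
when the scanner already meets the target (no realizable filter can
sharpen).

The data-driven estimate works on **group-averaged** images. Per
scanner, each spatially normalized volume is intensity-normalized
(divided by its global mean by default) and the cohort is averaged
voxelwise; averaging suppresses inter-subject variability and noise,
leaving resolution as the dominant difference between two scanners'
averages. The reference average is smoothed to the target resolution
by the quadrature rule, and the harmonization filter for the test
scanner is

    Theta* = argmax_Theta SSIM( I_ref_prepared, G(Theta) * I_test_avg )

over Theta = (FWHM_XY, FWHM_Z) in [0, upper_bound]^2.

## SSIM objective

SSIM is computed with Gaussian-weighted local statistics: window sigma
1.5 voxels with an 11x11x11 support, stabilizers C1 = (0.01 L)^2,
C2 = (0.03 L)^2. The dynamic range L defaults to the **reference**
image's max − min so the objective does not shift as the test image is
filtered during optimization (the alternative — taking L from both
images — makes the objective a moving target). Local statistics use
replicate (nearest) padding at the volume edge, consistent with the
filtering module, and the score is the mean of the local map over the
whole volume; an optional mask can restrict it (e.g. to a brain mask),
but the default is the plain whole-volume mean.

MSE, PSNR, NCC and MI are available for metric-comparison studies.
They are not used as objectives: MSE/PSNR are sensitive to global
intensity scaling, and NCC/MI, while often similar to SSIM, are less
stable in this setting.

## Optimization

Two stages, both deterministic:

1. **Grid search** over [0, upper_bound]^2 at a configurable step.
   Exact ties on a flat plateau resolve toward the least smoothing
   (smallest FWHM_XY, then smallest FWHM_Z).
2. **Bounded Nelder-Mead** refinement started at the grid optimum
   (parameter tolerance 1e-3 mm, initial simplex step half the grid
   step). The objective is evaluated through convolution and carries
   ~1e-8 numerical noise, which rules out finite-difference gradients;
   a derivative-free simplex is robust to it. The refined optimum is
   never allowed below the best grid value.

Upper bounds follow the target resolution: 6, 10 and 16 mm for
targets of 6, 8 and 10 mm. An estimate within 0.1 mm of the bound
raises a boundary flag (bound likely too tight); such results are
reported, flagged, never dropped. `estimate_filter` defaults to a
0.5 mm grid step, which resolves the ~1 mm uncertainty scale of the
SSIM surface; the validation harness uses a 2 mm step, because the
surface is unimodal (verified by the surface tests) so the grid only
needs to land in the basin of attraction and the simplex supplies the
final sub-0.1 mm accuracy at a quarter of the cost.

## Synthetic cohorts

The phantom is a deterministic piecewise-constant "brain": an
ellipsoidal gray-matter shell at 4x the white-matter level (the
conventional FDG brain-phantom contrast) with a sinusoidally folded
inner boundary providing edge structure, two zero-intensity
ventricles, zero background. Default geometry is template-space FDG
PET: 79x95x78 voxels at 2 mm isotropic.

Each simulated subject applies, in order:

| mechanism | parameter | default | rationale |
|---|---|---|---|
| global intensity scale | `subject_intensity_cv` | 0.05 | typical inter-subject global-uptake spread after intensity normalization |
| smooth regional field | `regional_variability_fwhm`, `_amplitude` | 20 mm, 0.05 | slowly varying regional metabolism differences |
| residual misregistration | `misreg_sd` | 0.5 mm/axis | plausible residual after template normalization; translation only, since small misalignment acts like mild extra blurring |
| scanner blur | scanner profile | — | the quantity under study |
| additive noise | `noise_sd_fraction` | 0.05 of mean GM | desk-scale surrogate for all post-reconstruction stochastic variability |

Noise is additive Gaussian in image space, not Poisson in projection
space: the protocol operates purely post-reconstruction, where
Gaussian image noise is the standard surrogate. Noise may leave small
negative background voxels, as real reconstructed PET images do; they
are left unclipped so that cohort averaging remains unbiased. The
true variability magnitudes of real multicenter cohorts are unknown;
these defaults are named config keys so sensitivity sweeps are
one-line changes.

Randomness: subject `i` of a cohort draws from
`numpy.random.default_rng([cohort_seed, i])`, so cohorts are
reproducible, subjects are order-independent, and a cohort can be
extended without reshuffling earlier subjects.

What the simulator does **not** emulate: anatomical variability
between subjects (one shared phantom), nonlinear registration error
(translation only), spatially varying (radially dependent) scanner
PSFs, attenuation/scatter artifacts, and tracer kinetics. Passing
validation therefore demonstrates correctness of the estimation
machinery under the four modelled difference sources, not performance
on real multicenter data.

## Validation design

Every scanner profile (HRRT 4.5/4.5 mm, Biograph 5.5/5.5, Discovery
5.5/6.0, HR+ 6.0/6.0; XY/Z FWHM) serves in turn as reference, every
other as test, at targets 6, 8 and 10 mm: 12 ordered pairs x 3
targets x 2 axes = 72 records. All cohorts are simulated from one
shared phantom — differences then arise only from the four modelled
sources, mirroring one population scanned on different machines.
Cohort sizes are the per-scanner subject counts (28, 69, 73, 70); the
diagnostic-group split is represented, when wanted, as two
independent draws with different seeds rather than as a biological
effect, since group differences in this setting are random effects.
Ground truth is the quadrature rule applied to the profile
resolutions, clamped at zero — near-target scanners (e.g. a 6 mm
scanner at a 6 mm target) have a true filter of exactly 0 and are the
known hard cases, because a sub-1 mm filter barely changes the image.

The summary reports per-target maximum and median absolute error and
the maximum restricted to records whose true filter is >= 5 mm (the
regime where substantial filtration is actually required), plus
per-test-scanner signed means to surface systematic biases. When no
record passes the restriction the restricted maximum is reported as
missing, not zero.

## Numerical choices and limitations

- Gaussian kernels are sampled and truncated at 4 sigma (truncation
  error < 1e-4); boundary handling is replicate-nearest everywhere.
- Sampled Gaussian kernels with FWHM below about 2 voxels deviate
  measurably from the continuous Gaussian (their discrete second
  moment is off by several percent), so the quadrature semigroup
  property holds to 1e-4 only for filters wider than ~2 voxels; the
  convolution-algebra tests therefore run on a 1 mm lattice. At the
  2 mm study spacing this affects only sub-4-mm filter components,
  and identically so on both sides of the matching, so the estimator
  is unaffected to first order.
- Volumes are processed in float64 and stored as float32 (intensities
  are relative activity; 1e-6 relative precision is ample).
- Impulse-response FWHM is measured by parabolic interpolation in
  log-intensity, which is exact for Gaussian samples.
- The protocol assumes both datasets are already spatially normalized
  to a common template; it does not perform registration.
- Estimation accuracy degrades as the required filter shrinks; at a
  6 mm target with near-target scanners, errors of a few mm are
  expected (and observed in the validation harness). The method is
  intended for moderate target resolutions.
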