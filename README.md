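# petharm

Data-driven resolution harmonization for multicenter brain FDG-PET.

Quantitative FDG-PET studies that pool images from several scanners
inherit each scanner's spatial resolution, and the resulting
inter-scanner variability confounds voxelwise and regional analyses.
The standard remedy — measuring each scanner's point-spread function
with phantom scans and smoothing everything to a common target
resolution — is unavailable in retrospective studies. `petharm`
estimates the required scanner-specific smoothing filters directly
from the subject images.

## Method

Images from each scanner are intensity-normalized and averaged; after
spatial normalization to a common template, the dominant difference
between two scanners' average images is their spatial resolution. The
reference average is smoothed to a chosen target resolution using the
quadrature rule for Gaussian resolutions,

    FWHM_filter = sqrt(FWHM_target² − FWHM_scanner²)   (per direction),

and the harmonization filter for a test scanner is the anisotropic
Gaussian Θ = (FWHM_XY, FWHM_Z), in mm, that maximizes the 3D
structural similarity index between the prepared reference average
and the filtered test average:

    Θ* = argmax_Θ SSIM( I_ref , G(Θ) ∗ I_test ).

The objective is maximized by an exhaustive grid search followed by
bounded Nelder–Mead refinement; the SSIM surface over (FWHM_XY,
FWHM_Z) is unimodal, so the optimization is reliable. A digital
brain-phantom simulator (gray/white contrast, inter-subject
variability, residual misregistration, scanner blur, noise) and a
cross-scanner validation harness are included, so the whole protocol
is testable without any real data. See `docs/methods.md` for details.

## Worked example

Estimate the filter that matches a sharper scanner's cohort to a
blurrier one, entirely on synthetic data:

```python
from petharm import (ScannerProfile, SyntheticCohortSpec, simulate_cohort,
                     average_cohort, prepare_reference, estimate_filter,
                     make_phantom, required_filter)

phantom = make_phantom()                      # 79x95x78 @ 2 mm
hrrt = ScannerProfile("HRRT", 4.5, 4.5)       # test: high resolution
hrplus = ScannerProfile("HR+", 6.0, 6.0)      # reference

ref_cohort = simulate_cohort(SyntheticCohortSpec(hrplus, 32, seed=1), phantom)
test_cohort = simulate_cohort(SyntheticCohortSpec(hrrt, 32, seed=2), phantom)

ref_avg = average_cohort(ref_cohort).mean_volume
test_avg = average_cohort(test_cohort).mean_volume

ref_8mm = prepare_reference(ref_avg, hrplus, target_fwhm=8.0)
result = estimate_filter(ref_8mm, test_avg, upper_bound=10.0)
print(f"estimated: ({result.theta.fwhm_xy:.2f}, {result.theta.fwhm_z:.2f}) mm, "
      f"SSIM {result.ssim:.4f}")
print(f"ground truth: {required_filter(8.0, 4.5):.2f} mm")
```

prints

```
estimated: (6.63, 6.60) mm, SSIM 0.9953
ground truth: 6.61 mm
```

i.e. the data-driven estimate recovers the phantom-derived 6.61 mm
filter to within a few hundredths of a mm; applying `(6.63, 6.60)` to the HRRT
volumes brings them to the HR+ cohort's 8 mm target resolution.

The same steps are available from a shell via the `petharm` CLI
(subcommands `estimate`, `apply`, `simulate`, `validate`, `ssim-map`),
e.g. `petharm estimate --ref ref.nii.gz --test test.nii.gz --target 8`.

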