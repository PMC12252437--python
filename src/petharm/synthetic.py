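"""Digital brain-phantom cohorts for end-to-end testing of the protocol.

A deterministic piecewise-constant phantom (gray-matter shell at 4x
the white-matter level, two zero-intensity ventricles, zero
background) stands in for an FDG-like activity distribution.  Each
simulated subject then passes through the four mechanisms that make
normalized images from two scanners differ:

1. inter-subject variability in metabolic activity — a global scalar
   plus a smooth multiplicative random field;
2. residual misregistration after spatial normalization — a small
   random rigid translation;
3. scanner resolution — anisotropic Gaussian blur at the scanner's
   (FWHM_XY, FWHM_Z);
4. image noise — additive Gaussian noise scaled to the gray-matter
   level.

Every subject draws from a generator seeded by (cohort seed, subject
index), so cohorts are reproducible, order-independent and extensible
without reshuffling earlier subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .filtering import FilterParams, ScannerProfile, apply_gaussian, fwhm_to_sigma
from .io import VolumeGrid

__all__ = [
    "SyntheticCohortSpec",
    "make_phantom",
    "simulate_subject",
    "simulate_cohort",
]

#: Smallest grid that still contains all phantom structures.
MIN_PHANTOM_DIM = 32


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Full recipe for one simulated scanner cohort.

    Parameters
    ----------
    scanner
        The scanner whose resolution blurs every subject.
    n_subjects
        Cohort size.
    shape, spacing
        Grid geometry; defaults match template-space FDG-PET images
        (79 x 95 x 78 voxels at 2 mm isotropic).
    gm_wm_ratio
        Gray-to-white-matter activity contrast (4:1, the conventional
        FDG brain-phantom contrast).
    subject_intensity_cv
        Coefficient of variation of the per-subject global intensity
        scalar (dimensionless).
    regional_variability_fwhm, regional_variability_amplitude
        Smoothness (mm FWHM) and relative amplitude of the smooth
        multiplicative inter-subject field.
    noise_sd_fraction
        Additive Gaussian noise SD as a fraction of the mean
        gray-matter intensity.
    misreg_sd
        Per-axis SD (mm) of the random rigid translation emulating
        residual spatial-normalization error.
    seed
        Cohort seed; subject ``i`` draws from a generator seeded by
        ``(seed, i)``.
    """

    scanner: ScannerProfile
    n_subjects: int
    shape: tuple[int, int, int] = (79, 95, 78)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    gm_wm_ratio: float = 4.0
    subject_intensity_cv: float = 0.05
    regional_variability_fwhm: float = 20.0
    regional_variability_amplitude: float = 0.05
    noise_sd_fraction: float = 0.05
    misreg_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.gm_wm_ratio <= 1:
            raise ValueError("gm_wm_ratio must be > 1")
        for name in (
            "subject_intensity_cv",
            "regional_variability_fwhm",
            "regional_variability_amplitude",
            "noise_sd_fraction",
            "misreg_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_scanner(self, scanner: ScannerProfile, n_subjects: int, seed: int):
        return replace(self, scanner=scanner, n_subjects=n_subjects, seed=seed)


def make_phantom(
    shape: tuple[int, int, int] = (79, 95, 78),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    gm_wm_ratio: float = 4.0,
) -> VolumeGrid:
    """Deterministic piecewise-constant brain-like phantom.

    An outer ellipsoidal "gray matter" shell at intensity
    ``gm_wm_ratio`` whose inner boundary is sinusoidally folded (a
    crude cortical ribbon), an inner "white matter" compartment at
    intensity 1, two small zero-intensity "ventricle" ellipsoids and
    zero background.  Identical arguments give bit-identical output.
    """
    if min(shape) < MIN_PHANTOM_DIM:
        raise ValueError(
            f"shape too small to contain the phantom structures "
            f"(min {MIN_PHANTOM_DIM} per axis, got {shape})"
        )
    shape = tuple(int(s) for s in shape)
    spacing = tuple(float(s) for s in spacing)
    idx = np.indices(shape, dtype=np.float64)
    center = [(n - 1) / 2.0 for n in shape]
    # physical mm coordinates relative to the grid center
    x = (idx[0] - center[0]) * spacing[0]
    y = (idx[1] - center[1]) * spacing[1]
    z = (idx[2] - center[2]) * spacing[2]
    # brain semi-axes: 84% of the half-extent per axis
    semi = [0.42 * shape[a] * spacing[a] for a in range(3)]
    u, v, w = x / semi[0], y / semi[1], z / semi[2]
    r = np.sqrt(u * u + v * v + w * w)

    # folded inner (GM/WM) boundary: sinusoidal perturbation in the
    # ellipsoid-normalized angular coordinates
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.arctan2(v, u)
        cos_theta = np.where(r > 0, w / np.maximum(r, 1e-12), 0.0)
    theta_ang = np.arccos(np.clip(cos_theta, -1.0, 1.0))
    r_inner = 0.62 + 0.08 * np.sin(6.0 * phi) * np.cos(4.0 * theta_ang)

    data = np.zeros(shape, dtype=np.float64)
    data[r <= 1.0] = gm_wm_ratio  # gray matter shell (filled below 1)
    data[r <= r_inner] = 1.0  # white matter core

    # two zero-intensity ventricles, offset laterally inside the core
    for sx in (-1.0, 1.0):
        vx = (x - sx * 0.18 * semi[0]) / (0.12 * semi[0])
        vy = y / (0.35 * semi[1])
        vz = (z - 0.08 * semi[2]) / (0.15 * semi[2])
        data[vx * vx + vy * vy + vz * vz <= 1.0] = 0.0

    return VolumeGrid(
        data=data,
        spacing=spacing,
        origin_note=f"synthetic phantom gm_wm_ratio={gm_wm_ratio}",
    )


def _subject_rng(spec: SyntheticCohortSpec, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed), int(subject_index)])


def simulate_subject(
    phantom: VolumeGrid, spec: SyntheticCohortSpec, subject_index: int
) -> VolumeGrid:
    """One simulated subject: variability, misregistration, blur, noise.

    A pure function of ``(phantom, spec, subject_index)``; the draw
    order (global scalar, smooth field, shift, noise) is fixed so the
    output is bit-reproducible.  Additive noise may leave small
    negative background voxels, as real reconstructed PET images do;
    they average out and are left untouched.
    """
    rng = _subject_rng(spec, subject_index)
    data = phantom.data
    gm_mask = data >= 0.5 * (1.0 + spec.gm_wm_ratio)

    # (1) inter-subject variability: global scalar and smooth field
    scalar = float(rng.normal(1.0, spec.subject_intensity_cv))
    scalar = max(scalar, 0.1)  # guard absurd negative draws at high CV
    img = data * scalar
    if spec.regional_variability_amplitude > 0:
        white = rng.standard_normal(data.shape)
        sigma_vox = [
            fwhm_to_sigma(spec.regional_variability_fwhm) / s for s in phantom.spacing
        ]
        smooth = ndi.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
        sd = smooth.std()
        if sd > 0:
            field_map = 1.0 + spec.regional_variability_amplitude * (
                (smooth - smooth.mean()) / sd
            )
            img = img * field_map

    # (2) residual misregistration: small rigid translation (spline)
    shift_mm = rng.normal(0.0, spec.misreg_sd, size=3)
    if np.any(shift_mm != 0.0):
        shift_vox = shift_mm / np.asarray(phantom.spacing)
        img = ndi.shift(img, shift_vox, order=3, mode="nearest")

    # (3) scanner resolution
    scanner_theta = FilterParams(spec.scanner.fwhm_xy, spec.scanner.fwhm_z)
    img = apply_gaussian(phantom.with_data(img), scanner_theta).data

    # (4) image noise, scaled to the subject's mean gray-matter level
    if spec.noise_sd_fraction > 0:
        sd = spec.noise_sd_fraction * float(img[gm_mask].mean())
        img = img + rng.normal(0.0, sd, size=img.shape)

    return VolumeGrid(
        data=img,
        spacing=phantom.spacing,
        origin_note=(
            f"synthetic subject {subject_index} scanner={spec.scanner.name} "
            f"seed={spec.seed}"
        ),
    )


def simulate_cohort(
    spec: SyntheticCohortSpec, phantom: VolumeGrid | None = None
) -> list[VolumeGrid]:
    """Simulate ``spec.n_subjects`` subjects (indices 0..n-1).

    A phantom may be passed in so several scanner cohorts share the
    same underlying activity distribution, as when the same population
    is scanned on different machines.
    """
    if phantom is None:
        phantom = make_phantom(spec.shape, spec.spacing, spec.gm_wm_ratio)
    return [simulate_subject(phantom, spec, i) for i in range(spec.n_subjects)]
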