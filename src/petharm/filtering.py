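"""Anisotropic Gaussian smoothing in mm-FWHM units and resolution arithmetic.

Scanner point-spread functions and harmonization filters are modelled
as separable 3D Gaussians, parameterized by their full width at half
maximum (FWHM) in mm: one in-plane value shared by the two transaxial
axes and one axial value.  Sequential Gaussian blurs combine in
quadrature, so the filter needed to bring a scanner of intrinsic
resolution ``FWHM_scanner`` to a coarser ``FWHM_target`` is

    FWHM_filter = sqrt(FWHM_target**2 - FWHM_scanner**2)

applied per direction with direction-specific scanner values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .io import VolumeGrid

__all__ = [
    "FWHM_PER_SIGMA",
    "FilterParams",
    "ScannerProfile",
    "fwhm_to_sigma",
    "sigma_to_fwhm",
    "apply_gaussian",
    "required_filter",
    "prepare_reference",
    "measure_profile_fwhm",
]

#: FWHM / sigma ratio of a Gaussian: 2 * sqrt(2 * ln 2).
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Kernel truncation radius in units of sigma; keeps truncation error < 1e-4.
GAUSSIAN_TRUNCATE = 4.0

#: Boundary handling for every spatial filter in the package.
BOUNDARY_MODE = "nearest"


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian FWHM to its standard deviation (same units)."""
    if fwhm < 0:
        raise ValueError(f"FWHM must be >= 0, got {fwhm}")
    return fwhm / FWHM_PER_SIGMA


def sigma_to_fwhm(sigma: float) -> float:
    """Exact inverse of :func:`fwhm_to_sigma`."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    return sigma * FWHM_PER_SIGMA


@dataclass(frozen=True)
class FilterParams:
    """Harmonization filter Theta = (FWHM_XY, FWHM_Z) in mm.

    ``fwhm_xy`` is applied identically along axes 0 and 1; ``fwhm_z``
    along axis 2.  ``(0, 0)`` is the identity filter.
    """

    fwhm_xy: float
    fwhm_z: float

    def __post_init__(self) -> None:
        for name in ("fwhm_xy", "fwhm_z"):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {val}")

    @property
    def is_identity(self) -> bool:
        return self.fwhm_xy == 0.0 and self.fwhm_z == 0.0

    def as_tuple(self) -> tuple[float, float]:
        return (self.fwhm_xy, self.fwhm_z)


@dataclass(frozen=True)
class ScannerProfile:
    """A scanner's effective intrinsic resolution (FWHM in mm).

    The 1-15 mm sanity range guards against unit mistakes (cm, voxels);
    clinical and research PET scanners all fall well inside it.
    Optional subject counts record the cohort sizes available per
    diagnostic group.
    """

    name: str
    fwhm_xy: float
    fwhm_z: float
    n_subjects_ad: int | None = None
    n_subjects_cn: int | None = None

    def __post_init__(self) -> None:
        for name in ("fwhm_xy", "fwhm_z"):
            val = getattr(self, name)
            if not (0.0 < val <= 15.0):
                raise ValueError(
                    f"{self.name}: {name}={val} mm outside the sane 1-15 mm range"
                )
            if val < 1.0:
                warnings.warn(
                    f"{self.name}: {name}={val} mm is below 1 mm — real PET "
                    "scanners resolve no finer; check the units",
                    stacklevel=3,
                )

    @property
    def n_subjects_total(self) -> int | None:
        if self.n_subjects_ad is None and self.n_subjects_cn is None:
            return None
        return (self.n_subjects_ad or 0) + (self.n_subjects_cn or 0)


def apply_gaussian(v: VolumeGrid, theta: FilterParams) -> VolumeGrid:
    """Separable Gaussian convolution of a volume, FWHM given in mm.

    Per-axis sigma in voxels is ``fwhm_to_sigma(component) / spacing``.
    Boundary handling is replicate-nearest; output shape and spacing
    equal the input's.  The identity filter returns a voxelwise-equal
    copy.
    """
    if theta.is_identity:
        return v.with_data(v.data.copy())
    sig_xy = fwhm_to_sigma(theta.fwhm_xy)
    sig_z = fwhm_to_sigma(theta.fwhm_z)
    sigma_vox = (
        sig_xy / v.spacing[0],
        sig_xy / v.spacing[1],
        sig_z / v.spacing[2],
    )
    out = ndi.gaussian_filter(
        v.data, sigma=sigma_vox, mode=BOUNDARY_MODE, truncate=GAUSSIAN_TRUNCATE
    )
    return v.with_data(out)


def required_filter(target_fwhm: float, scanner_fwhm: float, *, warn: bool = True) -> float:
    """Filter FWHM (mm) that brings a scanner to a coarser target resolution.

    Quadrature rule: ``sqrt(target**2 - scanner**2)``.  When the scanner
    resolution already meets or exceeds the target the result is clamped
    to 0 (with a warning), since no physically realizable smoothing can
    sharpen an image.
    """
    if target_fwhm <= 0 or scanner_fwhm <= 0:
        raise ValueError(
            f"target and scanner FWHM must be > 0, got {target_fwhm}, {scanner_fwhm}"
        )
    if target_fwhm <= scanner_fwhm:
        if warn and target_fwhm < scanner_fwhm:
            warnings.warn(
                f"scanner resolution {scanner_fwhm} mm exceeds target "
                f"{target_fwhm} mm; filter clamped to 0",
                stacklevel=2,
            )
        return 0.0
    return math.sqrt(target_fwhm**2 - scanner_fwhm**2)


def prepare_reference(
    ref_avg: VolumeGrid,
    scanner: ScannerProfile,
    target_fwhm: float,
    *,
    warn: bool = True,
) -> VolumeGrid:
    """Smooth a reference average to a desired target resolution.

    The quadrature rule is applied separately in the XY and Z
    directions with the reference scanner's direction-specific
    resolution; components are clamped to 0 where the scanner already
    meets the target.
    """
    theta = FilterParams(
        fwhm_xy=required_filter(target_fwhm, scanner.fwhm_xy, warn=warn),
        fwhm_z=required_filter(target_fwhm, scanner.fwhm_z, warn=warn),
    )
    return apply_gaussian(ref_avg, theta)


def measure_profile_fwhm(profile: np.ndarray, spacing: float) -> float:
    """Measure the FWHM of a single-peaked 1D profile, in mm.

    The peak height is refined by fitting a parabola through the three
    samples around the maximum; the two half-maximum crossings are then
    located by local quadratic (inverse-parabolic) interpolation,
    falling back to linear interpolation where the local curvature is
    degenerate.  Used to verify impulse responses of the Gaussian
    filter against their nominal width.
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.ndim != 1 or p.size < 5:
        raise ValueError("profile must be 1D with at least 5 samples")
    i = int(np.argmax(p))
    if i == 0 or i == p.size - 1:
        raise ValueError("peak lies on the profile boundary")
    if np.all(p[i - 1 : i + 2] > 0):  # log-parabola: exact for a Gaussian
        q = np.log(p[i - 1 : i + 2])
        denom = q[0] - 2.0 * q[1] + q[2]
        if denom < 0:
            delta = 0.5 * (q[0] - q[2]) / denom
            peak = math.exp(q[1] - 0.25 * (q[0] - q[2]) * delta)
        else:
            peak = p[i]
    else:
        denom = p[i - 1] - 2.0 * p[i] + p[i + 1]
        if denom < 0:
            delta = 0.5 * (p[i - 1] - p[i + 1]) / denom
            peak = p[i] - 0.25 * (p[i - 1] - p[i + 1]) * delta
        else:
            peak = p[i]
    half = peak / 2.0

    def crossing(j_below: int, j_above: int) -> float:
        # Half-max position between adjacent samples j_below (< half)
        # and j_above (>= half).  A Gaussian is exactly quadratic in
        # log-intensity, so the parabola is fitted to the log of the
        # three samples centered at j_above; linear interpolation on
        # the raw profile is the fallback for non-positive samples or
        # degenerate curvature.
        k = j_above
        if 1 <= k <= p.size - 2 and half > 0 and np.all(p[k - 1 : k + 2] > 0):
            q = np.log(p[k - 1 : k + 2])
            a = 0.5 * (q[0] - 2 * q[1] + q[2])
            b = 0.5 * (q[2] - q[0])
            c = q[1] - math.log(half)
            if abs(a) > 1e-12 * max(abs(b), 1.0):
                disc = b * b - 4 * a * c
                if disc >= 0:
                    for root in (
                        (-b + math.sqrt(disc)) / (2 * a),
                        (-b - math.sqrt(disc)) / (2 * a),
                    ):
                        x = k + root
                        if min(j_below, j_above) <= x <= max(j_below, j_above):
                            return x
        return j_below + (half - p[j_below]) / (p[j_above] - p[j_below]) * (
            j_above - j_below
        )

    j = i
    while j > 0 and p[j - 1] >= half:
        j -= 1
    if j == 0:
        raise ValueError("left half-maximum crossing not inside the profile")
    left = crossing(j - 1, j)

    j = i
    while j < p.size - 1 and p[j + 1] >= half:
        j += 1
    if j == p.size - 1:
        raise ValueError("right half-maximum crossing not inside the profile")
    right = crossing(j + 1, j)

    return float((right - left) * spacing)
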