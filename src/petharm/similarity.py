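"""Volumetric image similarity: 3D SSIM and the alternate metrics.

The harmonization objective is the mean structural similarity index
(SSIM) between two volumes on the same lattice, computed with
Gaussian-weighted local statistics (sigma 1.5 voxels, 11x11x11
support).  The local score at each voxel is

    S = (2 mu_x mu_y + C1)(2 cov_xy + C2)
        -------------------------------------
        (mu_x^2 + mu_y^2 + C1)(var_x + var_y + C2)

with stabilizers C1 = (k1 L)^2, C2 = (k2 L)^2 where L is the dynamic
range.  By default L is taken from the *reference* image, so the
objective does not move as the test image is filtered during
optimization.

MSE, PSNR, NCC and MI are provided for metric-comparison studies; SSIM
is the default objective because intensity-scaling sensitivity (MSE,
PSNR) and occasional instability (NCC, MI) make the alternates less
reliable for resolution matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .filtering import FilterParams, apply_gaussian
from .io import VolumeGrid

__all__ = [
    "SSIMParams",
    "SSIMComparator",
    "compute_ssim",
    "compute_alt_metric",
    "ssim_surface",
    "surface_to_frame",
]

ALT_METRICS = ("mse", "psnr", "ncc", "mi")


@dataclass(frozen=True)
class SSIMParams:
    """Parameters of the windowed SSIM computation.

    ``sigma`` (voxels) and ``half_width`` describe the Gaussian-weighted
    local window (default 1.5 and 5, i.e. 11^3 support); ``k1``/``k2``
    are the usual dimensionless stabilizer constants.  ``dynamic_range``
    defaults to ``max(ref) - min(ref)`` when left as None.  A uniform
    (box) window is available for sensitivity checks but is not the
    default.
    """

    sigma: float = 1.5
    half_width: int = 5
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float | None = None
    uniform_window: bool = False

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be > 0")
        if self.half_width < 3:
            raise ValueError("half_width must be >= 3")
        if self.dynamic_range is not None and self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def _window_filter(arr: np.ndarray, p: SSIMParams) -> np.ndarray:
    if p.uniform_window:
        return ndi.uniform_filter(arr, size=2 * p.half_width + 1, mode="nearest")
    return ndi.gaussian_filter(
        arr, sigma=p.sigma, mode="nearest", radius=p.half_width
    )


class SSIMComparator:
    """SSIM against a fixed reference volume, with cached reference stats.

    The optimizer evaluates SSIM many times against the same reference;
    precomputing the reference's local mean and variance roughly halves
    the per-evaluation cost.
    """

    def __init__(self, ref: VolumeGrid, params: SSIMParams | None = None):
        self.ref = ref
        self.params = params or SSIMParams()
        p = self.params
        L = p.dynamic_range
        if L is None:
            L = float(ref.data.max() - ref.data.min())
        if L <= 0:
            raise ValueError("zero dynamic range: reference image is constant")
        self.dynamic_range = L
        self.c1 = (p.k1 * L) ** 2
        self.c2 = (p.k2 * L) ** 2
        x = ref.data
        self._x = x
        self._ux = _window_filter(x, p)
        self._vx = _window_filter(x * x, p) - self._ux**2

    def local_map(self, test_data: np.ndarray) -> np.ndarray:
        """Per-voxel SSIM map against the cached reference."""
        p = self.params
        y = test_data
        uy = _window_filter(y, p)
        vy = _window_filter(y * y, p) - uy**2
        cov = _window_filter(self._x * y, p) - self._ux * uy
        num = (2.0 * self._ux * uy + self.c1) * (2.0 * cov + self.c2)
        den = (self._ux**2 + uy**2 + self.c1) * (self._vx + vy + self.c2)
        return num / den

    def score(self, test_data: np.ndarray, mask: np.ndarray | None = None) -> float:
        m = self.local_map(test_data)
        if mask is not None:
            return float(m[mask].mean())
        return float(m.mean())


def compute_ssim(
    ref: VolumeGrid,
    test: VolumeGrid,
    params: SSIMParams | None = None,
    mask: np.ndarray | None = None,
) -> float:
    """Mean SSIM between two volumes on identical lattices.

    Deterministic; returns a value in [-1, 1], equal to 1 iff the
    volumes are voxelwise identical.  ``mask`` optionally restricts the
    average to a region (e.g. a brain mask); the default is the whole
    volume.
    """
    if not ref.same_geometry(test):
        raise ValueError(
            f"shape/spacing mismatch: {ref.shape}/{ref.spacing} vs "
            f"{test.shape}/{test.spacing}"
        )
    return SSIMComparator(ref, params).score(test.data, mask=mask)


def compute_alt_metric(ref: VolumeGrid, test: VolumeGrid, metric: str) -> float:
    """MSE, PSNR (dB), NCC (Pearson r) or MI (nats, 64-bin histogram)."""
    if not ref.same_geometry(test):
        raise ValueError("shape/spacing mismatch")
    x = ref.data.ravel()
    y = test.data.ravel()
    if metric == "mse":
        return float(np.mean((x - y) ** 2))
    if metric == "psnr":
        mse = float(np.mean((x - y) ** 2))
        if mse == 0:
            return float("inf")
        L = float(x.max() - x.min())
        if L <= 0:
            raise ValueError("zero dynamic range for PSNR")
        return float(10.0 * np.log10(L**2 / mse))
    if metric == "ncc":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("NCC undefined for constant input")
        return float(np.corrcoef(x, y)[0, 1])
    if metric == "mi":
        return _mutual_information(x, y, bins=64)
    raise ValueError(f"unknown metric {metric!r}; expected one of {ALT_METRICS}")


def _mutual_information(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    # equal-width bins over each image's own range; MI in nats
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def ssim_surface(
    ref: VolumeGrid,
    test: VolumeGrid,
    xy_grid: np.ndarray,
    z_grid: np.ndarray,
    params: SSIMParams | None = None,
) -> np.ndarray:
    """SSIM over a 2D grid of (FWHM_XY, FWHM_Z) filter values in mm.

    Entry ``(i, j)`` is the SSIM between ``ref`` and ``test`` filtered
    with ``(xy_grid[i], z_grid[j])``.  Used both to localize the
    optimum and to inspect the shape of the objective (unimodality,
    XY/Z anti-correlation).
    """
    xy = np.asarray(xy_grid, dtype=np.float64)
    z = np.asarray(z_grid, dtype=np.float64)
    for g, name in ((xy, "xy_grid"), (z, "z_grid")):
        if g.size == 0:
            raise ValueError(f"{name} is empty")
        if np.any(g < 0):
            raise ValueError(f"{name} contains negative FWHM values")
        if np.any(np.diff(g) <= 0) and g.size > 1:
            raise ValueError(f"{name} must be strictly ascending")
    if not ref.same_geometry(test):
        raise ValueError("shape/spacing mismatch")
    comp = SSIMComparator(ref, params)
    surface = np.empty((xy.size, z.size), dtype=np.float64)
    for i, fx in enumerate(xy):
        for j, fz in enumerate(z):
            blurred = apply_gaussian(test, FilterParams(fx, fz))
            surface[i, j] = comp.score(blurred.data)
    return surface


def surface_to_frame(xy_grid, z_grid, surface):
    """Long-format table of an SSIM surface (fwhm_xy_mm, fwhm_z_mm, ssim)."""
    import pandas as pd

    xy = np.asarray(xy_grid, dtype=np.float64)
    z = np.asarray(z_grid, dtype=np.float64)
    rows = [
        {"fwhm_xy_mm": xy[i], "fwhm_z_mm": z[j], "ssim": surface[i, j]}
        for i in range(xy.size)
        for j in range(z.size)
    ]
    return pd.DataFrame(rows)
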