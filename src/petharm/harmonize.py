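"""The end-to-end harmonization protocol.

Given a set of spatially normalized volumes per scanner, the protocol
is:

1. intensity-normalize each volume and average per scanner;
2. smooth the reference average to a chosen target resolution;
3. find the anisotropic Gaussian filter Theta = (FWHM_XY, FWHM_Z) that
   maximizes SSIM between the prepared reference average and the
   filtered test average;
4. apply the estimated filter to every test volume.

The optimizer is two-stage: an exhaustive grid over
[0, upper_bound]^2 localizes the optimum, then a bounded Nelder-Mead
simplex refines it.  The objective is evaluated through convolution
and carries ~1e-8 numerical noise, which makes derivative-free
refinement the robust choice.

This method is intended for group-averaged images: averaging
suppresses subject variability and noise, which single-subject input
does not, so calling it with one volume per side is possible but
unsupported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .filtering import FilterParams, apply_gaussian
from .io import VolumeGrid
from .similarity import SSIMComparator, SSIMParams

__all__ = [
    "CohortAverage",
    "OptimizationResult",
    "normalize_intensity",
    "average_cohort",
    "estimate_filter",
    "apply_harmonization",
]

NORMALIZATION_MODES = ("global_mean", "masked_mean", "none")

#: Estimates closer than this (mm) to the upper bound are flagged.
BOUNDARY_TOL = 0.1


@dataclass
class CohortAverage:
    """Voxelwise mean of a scanner's intensity-normalized volumes."""

    mean_volume: VolumeGrid
    n_images: int
    normalization_mode: str

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")


@dataclass
class OptimizationResult:
    """Outcome of the two-stage SSIM maximization.

    ``theta`` is the estimated filter; ``ssim`` its objective value.
    ``converged`` reports stage-2 convergence (on failure the result
    falls back to the best grid point).  ``boundary`` flags an optimum
    within :data:`BOUNDARY_TOL` of the upper bound, a sign the bound
    was too tight.  The full stage-1 surface is retained for
    diagnostics and CSV export.
    """

    theta: FilterParams
    ssim: float
    converged: bool
    boundary: bool
    upper_bound: float
    n_evaluations: int
    grid_xy: np.ndarray = field(repr=False)
    grid_z: np.ndarray = field(repr=False)
    grid_scores: np.ndarray = field(repr=False)
    grid_theta: FilterParams | None = None


def normalize_intensity(v: VolumeGrid, mode: str = "global_mean") -> VolumeGrid:
    """Scale a volume so its mean over the chosen region is 1.

    ``global_mean`` divides by the mean over all voxels; ``masked_mean``
    by the mean over voxels above 20% of the volume maximum (a crude
    brain mask); ``none`` is the identity.
    """
    if mode == "none":
        return v.with_data(v.data.copy())
    if mode == "global_mean":
        denom = float(v.data.mean())
    elif mode == "masked_mean":
        mask = v.data > 0.2 * v.data.max()
        denom = float(v.data[mask].mean()) if mask.any() else 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}; expected one of {NORMALIZATION_MODES}")
    if denom <= 0:
        raise ValueError(f"non-positive normalization denominator ({denom})")
    return v.with_data(v.data / denom)


def average_cohort(volumes: list[VolumeGrid], mode: str = "global_mean") -> CohortAverage:
    """Voxelwise arithmetic mean of intensity-normalized volumes.

    Each volume is normalized individually before averaging, so every
    subject contributes with the same overall intensity scale.
    """
    if not volumes:
        raise ValueError("cannot average an empty cohort")
    first = volumes[0]
    for v in volumes[1:]:
        if not first.same_geometry(v):
            raise ValueError("all volumes must share shape and spacing")
    acc = np.zeros(first.shape, dtype=np.float64)
    for v in volumes:
        acc += normalize_intensity(v, mode).data
    acc /= len(volumes)
    return CohortAverage(
        mean_volume=first.with_data(acc, note=f"mean of {len(volumes)} volumes"),
        n_images=len(volumes),
        normalization_mode=mode,
    )


def _grid_points(upper_bound: float, grid_step: float) -> np.ndarray:
    pts = np.arange(0.0, upper_bound + 1e-9, grid_step)
    if pts[-1] < upper_bound - 1e-9:
        pts = np.append(pts, upper_bound)
    return pts


def estimate_filter(
    ref_avg: VolumeGrid,
    test_avg: VolumeGrid,
    upper_bound: float,
    params: SSIMParams | None = None,
    grid_step: float = 0.5,
) -> OptimizationResult:
    """Estimate the filter matching a test average to a reference average.

    Stage 1 evaluates SSIM on an exhaustive ``grid_step``-spaced grid
    over ``[0, upper_bound]^2`` (ties broken toward the least
    smoothing: smallest FWHM_XY, then smallest FWHM_Z).  Stage 2
    refines the best grid point with a bounded Nelder-Mead simplex
    (parameter tolerance 1e-3 mm).  Deterministic given its inputs;
    the refined objective is never below the best grid value.
    """
    if not ref_avg.same_geometry(test_avg):
        raise ValueError("reference and test averages must share shape and spacing")
    if upper_bound <= 0:
        raise ValueError("upper_bound must be > 0")
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")

    comp = SSIMComparator(ref_avg, params)
    n_eval = 0

    def objective(fwhm_xy: float, fwhm_z: float) -> float:
        nonlocal n_eval
        n_eval += 1
        blurred = apply_gaussian(test_avg, FilterParams(fwhm_xy, fwhm_z))
        return comp.score(blurred.data)

    # stage 1: exhaustive grid
    pts = _grid_points(upper_bound, grid_step)
    scores = np.empty((pts.size, pts.size), dtype=np.float64)
    for i, fx in enumerate(pts):
        for j, fz in enumerate(pts):
            scores[i, j] = objective(fx, fz)
    # np.argmax on the C-ordered array returns the first maximum, i.e.
    # smallest fwhm_xy then smallest fwhm_z on exact-tie plateaus
    i0, j0 = np.unravel_index(int(np.argmax(scores)), scores.shape)
    grid_theta = FilterParams(float(pts[i0]), float(pts[j0]))
    grid_best = float(scores[i0, j0])

    # stage 2: bounded derivative-free refinement from the grid optimum
    x0 = np.array(grid_theta.as_tuple())
    step = max(grid_step / 2.0, 0.25)
    simplex = [x0.copy()]
    for axis in range(2):
        vert = x0.copy()
        vert[axis] += step if vert[axis] + step <= upper_bound else -step
        vert[axis] = float(np.clip(vert[axis], 0.0, upper_bound))
        simplex.append(vert)
    res = minimize(
        lambda t: -objective(float(t[0]), float(t[1])),
        x0,
        method="Nelder-Mead",
        bounds=[(0.0, upper_bound)] * 2,
        options={
            "xatol": 1e-3,
            "fatol": 1e-10,
            "maxfev": 400,
            "initial_simplex": np.asarray(simplex),
        },
    )
    refined_score = -float(res.fun)
    converged = bool(res.success)
    if refined_score >= grid_best:
        theta = FilterParams(float(res.x[0]), float(res.x[1]))
        best = refined_score
    else:  # never return worse than the grid optimum
        theta, best = grid_theta, grid_best
        converged = False

    boundary = any(c >= upper_bound - BOUNDARY_TOL for c in theta.as_tuple())
    if boundary:
        warnings.warn(
            f"optimum {theta.as_tuple()} lies on the upper bound "
            f"{upper_bound} mm; the bound is likely too tight",
            stacklevel=2,
        )
    return OptimizationResult(
        theta=theta,
        ssim=best,
        converged=converged,
        boundary=boundary,
        upper_bound=float(upper_bound),
        n_evaluations=n_eval,
        grid_xy=pts,
        grid_z=pts.copy(),
        grid_scores=scores,
        grid_theta=grid_theta,
    )


def apply_harmonization(volumes: list[VolumeGrid], theta: FilterParams) -> list[VolumeGrid]:
    """Filter every volume with the estimated Theta, preserving order."""
    return [apply_gaussian(v, theta) for v in volumes]
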