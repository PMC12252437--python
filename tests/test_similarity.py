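import numpy as np
import pytest

from petharm import (
    FilterParams,
    SSIMParams,
    VolumeGrid,
    apply_gaussian,
    compute_alt_metric,
    compute_ssim,
    ssim_surface,
)
from petharm.similarity import SSIMComparator, surface_to_frame

from _oracles import mutual_information_bruteforce, ssim_bruteforce
from conftest import random_smooth_pair


def vol(data, spacing=(2.0, 2.0, 2.0)):
    return VolumeGrid(data, spacing)


class TestComputeSSIM:
    def test_self_similarity_is_exactly_one(self, small_phantom):
        assert compute_ssim(small_phantom, small_phantom) == 1.0

    def test_constant_images_closed_form(self):
        """For constant images the SSIM collapses to the luminance term."""
        a, b, L = 3.0, 5.0, 10.0
        x = vol(np.full((16, 16, 16), a))
        y = vol(np.full((16, 16, 16), b))
        c1 = (0.01 * L) ** 2
        expected = (2 * a * b + c1) / (a**2 + b**2 + c1)
        got = compute_ssim(x, y, SSIMParams(dynamic_range=L))
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        """Windowed SSIM equals a literal per-voxel re-implementation."""
        x, y = random_smooth_pair(seed)
        got = compute_ssim(vol(x), vol(y), SSIMParams(dynamic_range=1.0))
        expected = ssim_bruteforce(x, y, dynamic_range=1.0)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_matches_skimage_on_interior(self):
        """Interior-cropped mean agrees with scikit-image's SSIM exactly
        (same Gaussian window, constants and crop semantics)."""
        structural_similarity = pytest.importorskip(
            "skimage.metrics"
        ).structural_similarity
        x, y = random_smooth_pair(123)
        comp = SSIMComparator(vol(x), SSIMParams(dynamic_range=1.0))
        interior = comp.local_map(y)[5:-5, 5:-5, 5:-5].mean()
        sk = structural_similarity(
            x, y, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=1.0,
        )
        assert interior == pytest.approx(sk, abs=1e-12)

    def test_symmetric_with_explicit_dynamic_range(self):
        x, y = random_smooth_pair(3)
        p = SSIMParams(dynamic_range=1.0)
        assert compute_ssim(vol(x), vol(y), p) == pytest.approx(
            compute_ssim(vol(y), vol(x), p), abs=1e-12
        )

    def test_bounded_above_by_one_and_below_for_unequal(self):
        x, y = random_smooth_pair(4)
        s = compute_ssim(vol(x), vol(y), SSIMParams(dynamic_range=1.0))
        assert -1.0 <= s < 1.0

    def test_geometry_mismatch_rejected(self):
        x = vol(np.zeros((16, 16, 16)))
        y = vol(np.zeros((16, 16, 17)))
        with pytest.raises(ValueError, match="mismatch"):
            compute_ssim(x, y)
        z = vol(np.zeros((16, 16, 16)), spacing=(2, 2, 3))
        with pytest.raises(ValueError, match="mismatch"):
            compute_ssim(x, z)

    def test_zero_dynamic_range_rejected(self):
        x = vol(np.full((16, 16, 16), 2.0))
        with pytest.raises(ValueError, match="dynamic range"):
            compute_ssim(x, x)

    def test_mask_restricts_average(self, small_phantom):
        other = apply_gaussian(small_phantom, FilterParams(6, 6))
        mask = small_phantom.data > 0
        full = compute_ssim(small_phantom, other)
        masked = compute_ssim(small_phantom, other, mask=mask)
        assert masked != full

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SSIMParams(k1=0)
        with pytest.raises(ValueError):
            SSIMParams(half_width=2)
        with pytest.raises(ValueError):
            SSIMParams(dynamic_range=0.0)


class TestAltMetrics:
    def test_identical_volumes(self, small_phantom):
        assert compute_alt_metric(small_phantom, small_phantom, "mse") == 0.0
        assert compute_alt_metric(small_phantom, small_phantom, "ncc") == pytest.approx(1.0)

    def test_ncc_scale_invariance(self, small_phantom):
        doubled = small_phantom.with_data(2.0 * small_phantom.data)
        assert compute_alt_metric(small_phantom, doubled, "ncc") == pytest.approx(1.0)

    def test_ncc_constant_input_rejected(self):
        c = vol(np.full((16, 16, 16), 3.0))
        x = vol(np.arange(16**3, dtype=float).reshape(16, 16, 16))
        with pytest.raises(ValueError, match="constant"):
            compute_alt_metric(x, c, "ncc")

    def test_mi_matches_histogram_oracle(self):
        rng = np.random.default_rng(11)
        x = vol(rng.integers(0, 8, (12, 12, 12)).astype(float))
        y = vol(rng.integers(0, 8, (12, 12, 12)).astype(float))
        got = compute_alt_metric(x, y, "mi")
        assert got == pytest.approx(mutual_information_bruteforce(x.data, y.data), abs=1e-12)

    def test_psnr_definition(self):
        x, y = random_smooth_pair(5)
        mse = compute_alt_metric(vol(x), vol(y), "mse")
        psnr = compute_alt_metric(vol(x), vol(y), "psnr")
        L = x.max() - x.min()
        assert psnr == pytest.approx(10 * np.log10(L**2 / mse))

    def test_unknown_metric_rejected(self, small_phantom):
        with pytest.raises(ValueError, match="unknown metric"):
            compute_alt_metric(small_phantom, small_phantom, "ssim2")


class TestSSIMSurface:
    def test_planted_blur_argmax_recovered(self, small_phantom):
        """A noiselessly planted filter is the surface argmax."""
        planted = (4.0, 6.0)
        ref = apply_gaussian(small_phantom, FilterParams(*planted))
        grid = [0.0, 2.0, 4.0, 6.0, 8.0]
        surface = ssim_surface(ref, small_phantom, grid, grid)
        i, j = np.unravel_index(np.argmax(surface), surface.shape)
        assert (grid[i], grid[j]) == planted

    def test_single_point_grid_equals_direct_ssim(self, small_phantom):
        ref = apply_gaussian(small_phantom, FilterParams(3.0, 3.0))
        surface = ssim_surface(ref, small_phantom, [3.0], [3.0])
        assert surface.shape == (1, 1)
        direct = compute_ssim(ref, apply_gaussian(small_phantom, FilterParams(3.0, 3.0)))
        assert surface[0, 0] == pytest.approx(direct, abs=1e-12)

    def test_noiseless_surface_is_unimodal(self, small_phantom):
        """No strict 4-neighborhood local maximum besides the global one."""
        ref = apply_gaussian(small_phantom, FilterParams(5.0, 5.0))
        grid = np.arange(0.0, 10.5, 1.0)
        s = ssim_surface(ref, small_phantom, grid, grid)
        n_local_max = 0
        for i in range(s.shape[0]):
            for j in range(s.shape[1]):
                neighbors = []
                if i > 0:
                    neighbors.append(s[i - 1, j])
                if i < s.shape[0] - 1:
                    neighbors.append(s[i + 1, j])
                if j > 0:
                    neighbors.append(s[i, j - 1])
                if j < s.shape[1] - 1:
                    neighbors.append(s[i, j + 1])
                if all(s[i, j] > nb for nb in neighbors):
                    n_local_max += 1
        assert n_local_max == 1

    def test_invalid_grids_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            ssim_surface(small_phantom, small_phantom, [], [0.0])
        with pytest.raises(ValueError):
            ssim_surface(small_phantom, small_phantom, [-1.0, 2.0], [0.0])
        with pytest.raises(ValueError):
            ssim_surface(small_phantom, small_phantom, [2.0, 1.0], [0.0])

    def test_surface_frame_layout(self):
        xy, z = [0.0, 1.0], [0.0, 1.0, 2.0]
        surface = np.arange(6, dtype=float).reshape(2, 3)
        frame = surface_to_frame(xy, z, surface)
        assert list(frame.columns) == ["fwhm_xy_mm", "fwhm_z_mm", "ssim"]
        assert len(frame) == 6
        assert frame["ssim"].tolist() == [0, 1, 2, 3, 4, 5]
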