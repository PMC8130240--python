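"""Lucas-Kanade solver oracles: gradients, normal equations, pyramid, flow."""

import numpy as np
import pytest

import lkdose as lk
from lkdose.lk import (
    LKParams,
    build_pyramid,
    lk_normal_system,
    smallest_eigenvalue_sym3,
    solve_gated_sym3,
    upsample_field,
    window_kernels,
)


class TestSpatialGradients:
    def test_constant_is_zero(self):
        gz, gy, gx = lk.spatial_gradients(np.full((4, 5, 6), 9.0))
        assert not gz.any() and not gy.any() and not gx.any()

    def test_linear_ramp_closed_form(self):
        z, y, x = np.meshgrid(*(np.arange(n, dtype=float) for n in (4, 5, 6)), indexing="ij")
        gz, gy, gx = lk.spatial_gradients(3.0 * x)
        assert np.allclose(gx, 3.0)  # exact everywhere incl. one-sided borders
        assert np.allclose(gz, 0.0) and np.allclose(gy, 0.0)

    def test_axis_separation(self):
        z, y, x = np.meshgrid(*(np.arange(n, dtype=float) for n in (4, 5, 6)), indexing="ij")
        gz, gy, gx = lk.spatial_gradients(2.0 * y)
        assert np.allclose(gy, 2.0)
        assert not gx.any() and not gz.any()

    def test_short_axis_rejected(self):
        with pytest.raises(ValueError):
            lk.spatial_gradients(np.zeros((1, 5, 5)))


class TestEigenSolve:
    def test_smallest_eigenvalue_matches_lapack(self, rng):
        g = rng.standard_normal((500, 3))
        a = np.einsum("ni,nj->nij", g, g) + 0.3 * np.einsum(
            "ni,nj->nij", rng.standard_normal((500, 3)), rng.standard_normal((500, 3))
        )
        a = (a + a.transpose(0, 2, 1)) / 2
        expected = np.linalg.eigvalsh(a)[:, 0]
        got = smallest_eigenvalue_sym3(
            a[:, 0, 0], a[:, 0, 1], a[:, 0, 2], a[:, 1, 1], a[:, 1, 2], a[:, 2, 2]
        )
        assert np.allclose(got, expected, atol=1e-8)

    def test_well_conditioned_solve_matches_numpy(self, rng):
        g = rng.standard_normal((50, 3, 3))
        a = np.einsum("nki,nkj->nij", g, g) + 0.5 * np.eye(3)  # SPD
        b = rng.standard_normal((50, 3))
        got = solve_gated_sym3(
            (a[:, 0, 0], a[:, 0, 1], a[:, 0, 2], a[:, 1, 1], a[:, 1, 2], a[:, 2, 2]),
            b,
            eigen_threshold=1e-8,
        )
        assert np.allclose(got, np.linalg.solve(a, b[..., None])[..., 0], atol=1e-8)

    def test_zero_tensor_gives_zero(self):
        zeros = tuple(np.zeros(4) for _ in range(6))
        out = solve_gated_sym3(zeros, np.ones((4, 3)), 1e-4)
        assert not out.any()


def brute_force_normal_system(ref, warped, radius, sigma):
    """Explicit-loop oracle for the per-voxel weighted normal equations."""
    gt = warped - ref
    gz, gy, gx = np.gradient(warped, axis=(0, 1, 2))
    g = np.stack([gz, gy, gx], axis=-1)
    shape = ref.shape
    offs = range(-radius, radius + 1)
    raw = np.exp(
        -np.array([oz**2 + oy**2 + ox**2 for oz in offs for oy in offs for ox in offs])
        / (2 * sigma**2)
    )
    weights = raw / raw.sum()
    a = np.zeros((*shape, 3, 3))
    b = np.zeros((*shape, 3))
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                w_idx = 0
                for oz in offs:
                    for oy in offs:
                        for ox in offs:
                            w = weights[w_idx]
                            w_idx += 1
                            z, y, x = i + oz, j + oy, k + ox
                            if not (0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]):
                                continue
                            gv = g[z, y, x]
                            a[i, j, k] += w * np.outer(gv, gv)
                            b[i, j, k] += w * gv * gt[z, y, x]
    return a, b


class TestNormalSystemOracle:
    def test_matches_explicit_loop_on_toy_volume(self, rng):
        """Windowed tensor/rhs equal the brute-force oracle on a 9^3 pair."""
        ref = rng.normal(0, 100, (9, 9, 9))
        warped = ref + rng.normal(0, 20, (9, 9, 9))
        radius, sigma = 2, 1.0
        (azz, azy, azx, ayy, ayx, axx), (bz, by, bx) = lk_normal_system(
            ref, warped, radius, sigma
        )
        a_o, b_o = brute_force_normal_system(ref, warped, radius, sigma)
        assert np.allclose(azz, a_o[..., 0, 0], atol=1e-8)
        assert np.allclose(azy, a_o[..., 0, 1], atol=1e-8)
        assert np.allclose(azx, a_o[..., 0, 2], atol=1e-8)
        assert np.allclose(ayy, a_o[..., 1, 1], atol=1e-8)
        assert np.allclose(ayx, a_o[..., 1, 2], atol=1e-8)
        assert np.allclose(axx, a_o[..., 2, 2], atol=1e-8)
        assert np.allclose(bz, b_o[..., 0], atol=1e-8)
        assert np.allclose(by, b_o[..., 1], atol=1e-8)
        assert np.allclose(bx, b_o[..., 2], atol=1e-8)

    def test_window_weights_sum_to_one(self):
        for r, s in ((1, 0.5), (3, 1.5), (4, 2.0)):
            ks = window_kernels(r, s)
            total = np.einsum("i,j,k->", *ks)
            assert total == pytest.approx(1.0, abs=1e-12)


class TestLKFlowLevel:
    def test_identical_volumes_zero_field(self, small_volume):
        f = lk.lk_flow_level(small_volume, small_volume, LKParams(pyramid_levels=1))
        assert np.abs(f.disp).max() < 1e-9

    def test_ramp_subvoxel_translation_recovered(self, ramp_pair):
        """LK is exact on affine intensity profiles: 0.5-voxel shift along x is
        recovered to 1e-3 voxel in one level (interior, two window diameters in)."""
        ref, flt = ramp_pair
        f = lk.lk_flow_level(ref, flt, LKParams(pyramid_levels=1))
        interior = f.disp[2:-2, 6:-6, 6:-6]
        assert np.abs(interior[..., 2] - 0.5).max() < 1e-3
        assert np.abs(interior[..., :2]).max() < 1e-3

    def test_constant_region_zero_update(self, rng):
        """Texture-free aperture-problem case: no update where nothing varies."""
        data = np.zeros((9, 24, 24))
        data[:, :, 16:] = rng.normal(0, 100, (9, 24, 8))  # texture only on the right
        ref = lk.ImageVolume(data, (1, 1, 1))
        flt = lk.ImageVolume(data + 0.0, (1, 1, 1))
        flt.data[:, :, 16:] += 5.0
        f = lk.lk_flow_level(ref, flt, LKParams(pyramid_levels=1, iters_per_level=1))
        assert np.abs(f.disp[:, :, :10]).max() == 0.0

    def test_shape_mismatch_raises(self, small_volume):
        other = lk.ImageVolume(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(lk.GeometryError):
            lk.lk_flow_level(small_volume, other, LKParams())


class TestBuildPyramid:
    def test_single_level_is_input(self, small_volume):
        assert build_pyramid(small_volume, 1) == [small_volume]

    def test_inplane_halving_512(self):
        """Clinical-resolution slices halve 512 -> 256 in-plane."""
        vol = lk.ImageVolume(np.zeros((2, 512, 512)), (2.5, 1.0, 1.0))
        pyr = build_pyramid(vol, 2)
        assert pyr[1].shape == (2, 256, 256)  # z kept: < 8 slices
        assert pyr[1].spacing == (2.5, 2.0, 2.0)

    def test_slice_axis_halves_only_with_enough_slices(self):
        vol = lk.ImageVolume(np.zeros((16, 64, 64)), (2.5, 1, 1))
        pyr = build_pyramid(vol, 3)
        assert pyr[1].shape == (8, 32, 32)
        assert pyr[2].shape == (4, 16, 16)  # 8 slices -> still halved once more
        assert pyr[1].spacing == (5.0, 2.0, 2.0)

    def test_constant_volume_stays_constant(self):
        vol = lk.ImageVolume(np.full((16, 64, 64), 7.0), (1, 1, 1))
        for level in build_pyramid(vol, 3):
            assert np.allclose(level.data, 7.0)

    def test_too_many_levels_rejected(self):
        vol = lk.ImageVolume(np.zeros((4, 8, 8)), (1, 1, 1))
        with pytest.raises(ValueError, match="levels"):
            build_pyramid(vol, 3)  # second halving would drop below 4 in-plane


class TestPyramidRegister:
    def test_self_registration_near_zero(self, rng):
        data = rng.normal(0, 60, (16, 48, 48))
        vol = lk.ImageVolume(data, (2.5, 1, 1))
        f = lk.pyramid_lk_register(vol, vol, LKParams())
        mags = f.magnitude_voxels()
        assert mags.mean() < 0.05
        assert mags.max() < 0.5

    def test_translation_equivariance(self, rng):
        """Registering shifted copies gives the shifted field on the interior."""
        from scipy.ndimage import gaussian_filter

        base = gaussian_filter(rng.normal(0, 1, (12, 40, 40)), 1.2) * 100
        ref = lk.ImageVolume(base, (1, 1, 1))
        flt = lk.ImageVolume(np.roll(base, 1, axis=2), (1, 1, 1))
        f1 = lk.pyramid_lk_register(ref, flt, LKParams(pyramid_levels=1, iters_per_level=3))
        ref2 = lk.ImageVolume(np.roll(base, 2, axis=1), (1, 1, 1))
        flt2 = lk.ImageVolume(np.roll(np.roll(base, 1, axis=2), 2, axis=1), (1, 1, 1))
        f2 = lk.pyramid_lk_register(ref2, flt2, LKParams(pyramid_levels=1, iters_per_level=3))
        sl = (slice(3, -3), slice(8, -6), slice(8, -8))
        shifted = np.roll(f1.disp, 2, axis=1)
        assert np.allclose(f2.disp[sl], shifted[sl], atol=0.15)

    def test_upsample_field_scales_displacements(self):
        coarse = lk.DeformationField(
            np.tile([1.0, 0.5, -0.5], (4, 8, 8, 1)), (5.0, 2.0, 2.0)
        )
        fine = lk.ImageVolume(np.zeros((8, 16, 16)), (2.5, 1.0, 1.0))
        up = upsample_field(coarse, fine)
        assert np.allclose(up.disp[..., 0], 2.0)
        assert np.allclose(up.disp[..., 1], 1.0)
        assert np.allclose(up.disp[..., 2], -1.0)


class TestJacobianDiagnostic:
    def test_smooth_field_no_folding(self):
        from lkdose.phantom import PhantomSpec, make_field

        f = make_field(PhantomSpec(shape=(24, 48, 48)))
        assert lk.negative_jacobian_count(f) == 0

    def test_folding_detected(self):
        disp = np.zeros((8, 8, 8, 3))
        disp[3, :, :, 0] = 3.0
        disp[5, :, :, 0] = -3.0  # mapping reverses order along z
        f = lk.DeformationField(disp, (1, 1, 1))
        assert lk.negative_jacobian_count(f) > 0
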