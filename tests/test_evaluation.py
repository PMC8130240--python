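"""Similarity metrics: landmark distance, masked RMSE, gamma analysis, DVH."""

import numpy as np
import pytest

import lkdose as lk
from lkdose.evaluation import (
    GammaParams,
    compare_accumulation,
    dose_at_volume,
    dvh,
    gamma_slice,
    gamma_study,
    landmark_distance,
    rmse_within_mask,
)


class TestLandmarkDistance:
    def test_identical_points_zero(self):
        pts = np.array([[1.0, 2.0, 3.0]])
        lm = lk.LandmarkSet(["a"], pts, pts.copy())
        assert landmark_distance(lm).mean_mm == 0.0

    def test_euclidean_norm(self):
        lm = lk.LandmarkSet(["a"], np.zeros((1, 3)), np.array([[1.0, 2.0, 2.0]]))
        assert landmark_distance(lm).mean_mm == pytest.approx(3.0)

    def test_field_maps_reference_points(self):
        """A uniform one-voxel x-shift field predicts floating = ref + spacing."""
        f = lk.DeformationField(np.tile([0.0, 0.0, 1.0], (6, 10, 10, 1)), (2.5, 1.0, 1.0))
        ref = np.array([[5.0, 4.0, 4.0], [7.5, 6.0, 2.0]])
        lm = lk.LandmarkSet(["a", "b"], ref, ref + [0.0, 0.0, 1.0])
        s = landmark_distance(lm, f)
        assert s.mean_mm == pytest.approx(0.0, abs=1e-9)
        s2 = landmark_distance(lm)
        assert s2.mean_mm == pytest.approx(1.0)


class TestRMSE:
    def _mask(self, shape):
        m = np.zeros(shape, dtype=bool)
        m[:, 2:-2, 2:-2] = True
        return lk.StructureMask("body", m, (1, 1, 1))

    def test_identical_zero(self, small_volume):
        m = self._mask(small_volume.shape)
        assert rmse_within_mask(small_volume, small_volume, m) == 0.0

    def test_constant_offset(self, small_volume):
        m = self._mask(small_volume.shape)
        reg = lk.ImageVolume(small_volume.data + 10.0, small_volume.spacing)
        assert rmse_within_mask(small_volume, reg, m) == pytest.approx(10.0)

    def test_half_offset_hand_value(self):
        ref = lk.ImageVolume(np.zeros((4, 10, 10)), (1, 1, 1))
        reg = lk.ImageVolume(np.zeros((4, 10, 10)), (1, 1, 1))
        m = self._mask((4, 10, 10))
        sel = np.argwhere(m.mask)
        half = sel[: len(sel) // 2]
        reg.data[tuple(half.T)] = 10.0
        assert rmse_within_mask(ref, reg, m) == pytest.approx(np.sqrt(50.0))

    def test_empty_mask_rejected(self, small_volume):
        empty = lk.StructureMask("body", np.zeros(small_volume.shape, bool), (1, 1, 1))
        with pytest.raises(ValueError):
            rmse_within_mask(small_volume, small_volume, empty)


def brute_force_gamma(ref, ev, spacing_yx, params, mask):
    """Exhaustive per-pixel gamma search oracle (explicit loops, same grid)."""
    from scipy.ndimage import map_coordinates

    sy, sx = spacing_yx
    nsteps = int(np.floor(params.radius / params.step + 1e-9))
    gamma = np.full(ref.shape, np.nan)
    for iy in range(ref.shape[0]):
        for ix in range(ref.shape[1]):
            if not mask[iy, ix]:
                continue
            rv = ref[iy, ix]
            if params.mode == "local":
                denom = params.dose_crit_pct / 100.0 * max(abs(rv), params.local_floor)
            else:
                sel = ref[mask]
                denom = params.dose_crit_pct / 100.0 * max(sel.max() - sel.min(), params.local_floor)
            best = np.inf
            for oy in range(-nsteps, nsteps + 1):
                for ox in range(-nsteps, nsteps + 1):
                    dy, dx = oy * params.step, ox * params.step
                    dist = np.hypot(dy, dx)
                    if dist > params.radius + 1e-9:
                        continue
                    v = map_coordinates(
                        ev, [[iy + dy / sy], [ix + dx / sx]], order=1, mode="nearest"
                    )[0]
                    g2 = (dist / params.dist_crit_mm) ** 2 + ((v - rv) / denom) ** 2
                    best = min(best, g2)
            gamma[iy, ix] = np.sqrt(best)
    return gamma


class TestGammaSlice:
    toy_params = GammaParams(search_radius_mm=3.0, search_step_mm=0.5)

    def test_identical_slices_all_pass(self, rng):
        ref = rng.uniform(50, 200, (16, 16))
        gmap, rate = gamma_slice(ref, ref, (1.0, 1.0), self.toy_params)
        assert rate == 100.0
        assert np.nanmax(gmap) == 0.0

    def test_exact_two_percent_boundary(self):
        """A flat 2% offset with zero spatial advantage gives gamma exactly 1."""
        ref = np.full((8, 8), 100.0)
        ev = np.full((8, 8), 102.0)
        gmap, rate = gamma_slice(ref, ev, (1.0, 1.0), self.toy_params)
        assert np.allclose(gmap, 1.0)
        assert rate == 100.0

    def test_matches_brute_force_oracle(self, rng):
        ref = rng.uniform(20, 300, (16, 16))
        ev = ref + rng.normal(0, 6, (16, 16))
        mask = rng.random((16, 16)) > 0.2
        params = self.toy_params
        gmap, _ = gamma_slice(ref, ev, (1.0, 2.0), params, mask=mask)
        oracle = brute_force_gamma(ref, ev, (1.0, 2.0), params, mask)
        sel = ~np.isnan(oracle)
        assert np.allclose(gmap[sel], oracle[sel], atol=1e-6)
        assert np.array_equal(np.isnan(gmap), np.isnan(oracle))

    def test_cap_preserves_pass_rate(self, rng):
        ref = rng.uniform(20, 300, (16, 16))
        ev = ref + rng.normal(0, 15, (16, 16))
        exact = GammaParams(search_radius_mm=3.0, search_step_mm=0.5)
        capped = GammaParams(search_radius_mm=3.0, search_step_mm=0.5, gamma_cap=1.0)
        _, r1 = gamma_slice(ref, ev, (1.0, 1.0), exact)
        _, r2 = gamma_slice(ref, ev, (1.0, 1.0), capped)
        assert r1 == r2

    def test_global_mode_offset_invariant(self, rng):
        ref = rng.uniform(50, 250, (12, 12))
        ev = ref + rng.normal(0, 4, (12, 12))
        p = GammaParams(mode="global", search_radius_mm=3.0, search_step_mm=0.5)
        _, r1 = gamma_slice(ref, ev, (1, 1), p)
        _, r2 = gamma_slice(ref + 500.0, ev + 500.0, (1, 1), p)
        assert r1 == pytest.approx(r2)

    def test_local_mode_scale_invariant(self, rng):
        ref = rng.uniform(50, 250, (12, 12))
        ev = ref + rng.normal(0, 4, (12, 12))
        p = GammaParams(search_radius_mm=3.0, search_step_mm=0.5)
        _, r1 = gamma_slice(ref, ev, (1, 1), p)
        _, r2 = gamma_slice(3.0 * ref, 3.0 * ev, (1, 1), p)
        assert r1 == pytest.approx(r2)

    def test_degenerate_mask_flagged(self):
        gmap, rate = gamma_slice(
            np.ones((8, 8)), np.ones((8, 8)), (1, 1), self.toy_params, mask=np.zeros((8, 8), bool)
        )
        assert np.isnan(rate)

    def test_param_invariants(self):
        with pytest.raises(ValueError):
            GammaParams(dose_crit_pct=0)
        with pytest.raises(ValueError):
            GammaParams(search_radius_mm=1.0)  # < dist criterion
        with pytest.raises(ValueError):
            GammaParams(search_step_mm=1.0)  # > dist/4


class TestGammaStudy:
    def test_identical_study_scores_100(self, rng):
        data = rng.uniform(0, 200, (4, 12, 12))
        vol = lk.ImageVolume(data, (2.5, 1, 1))
        m = np.zeros((4, 12, 12), bool)
        m[:, 3:-3, 3:-3] = True
        mask = lk.StructureMask("body", m, (2.5, 1, 1))
        rep = gamma_study(vol, vol, mask, GammaParams(search_radius_mm=3.0, search_step_mm=0.5))
        assert rep.study_score_pct == 100.0
        assert len(rep.per_slice_pct) == 4

    def test_average_over_slices(self, monkeypatch):
        """Study value is the plain mean of per-slice pass rates."""
        import lkdose.evaluation as ev

        rates = iter([100.0, 50.0])
        monkeypatch.setattr(
            ev, "gamma_slice", lambda *a, **k: (None, next(rates))
        )
        vol = lk.ImageVolume(np.zeros((2, 8, 8)), (1, 1, 1))
        mask = lk.StructureMask("body", np.ones((2, 8, 8), bool), (1, 1, 1))
        rep = ev.gamma_study(vol, vol, mask, GammaParams(search_radius_mm=3.0, search_step_mm=0.5))
        assert rep.study_score_pct == pytest.approx(75.0)

    def test_no_evaluable_slice_raises(self):
        vol = lk.ImageVolume(np.zeros((2, 8, 8)), (1, 1, 1))
        mask = lk.StructureMask("body", np.zeros((2, 8, 8), bool), (1, 1, 1))
        with pytest.raises(ValueError):
            gamma_study(vol, vol, mask, GammaParams(search_radius_mm=3.0, search_step_mm=0.5))


class TestDVH:
    def _toy(self):
        # 10 masked voxels of exactly 1 cm^3 (10 x 10 x 10 mm) with doses 1..10 Gy
        data = np.zeros((2, 2, 10))
        data[0, 0] = np.arange(1, 11)
        dose = lk.DoseGrid(data, (10.0, 10.0, 10.0))
        mask = np.zeros_like(data, dtype=bool)
        mask[0, 0] = True
        return dose, lk.StructureMask("oar", mask, (10.0, 10.0, 10.0))

    def test_sorted_voxel_oracle(self):
        dose, mask = self._toy()
        assert dose_at_volume(dose, mask, 2.0) == pytest.approx(9.0)
        assert dose_at_volume(dose, mask, 0.5) == pytest.approx(10.0)
        assert dose_at_volume(dose, mask, 10.0) == pytest.approx(1.0)

    def test_uniform_dose_identity(self):
        dose = lk.DoseGrid(np.full((2, 4, 4), 7.0), (10, 10, 10))
        mask = lk.StructureMask("oar", np.ones((2, 4, 4), bool), (10, 10, 10))
        for v in (0.1, 2.0, 20.0):
            assert dose_at_volume(dose, mask, v) == pytest.approx(7.0)

    def test_monotone_in_volume(self, rng):
        dose = lk.DoseGrid(rng.uniform(0, 80, (4, 8, 8)), (2.5, 2.0, 2.0))
        mask = lk.StructureMask("oar", rng.random((4, 8, 8)) > 0.3, (2.5, 2.0, 2.0))
        vs = np.linspace(0.05, 1.0, 8)
        dv = [dose_at_volume(dose, mask, v) for v in vs]
        assert all(a >= b - 1e-12 for a, b in zip(dv, dv[1:]))

    def test_volume_too_large_rejected(self):
        dose, mask = self._toy()
        with pytest.raises(ValueError, match="cm"):
            dose_at_volume(dose, mask, 100.0)

    def test_dvh_curve_monotone_nonincreasing(self, rng):
        dose = lk.DoseGrid(rng.uniform(0, 60, (3, 6, 6)), (2.5, 2.0, 2.0))
        mask = lk.StructureMask("oar", np.ones((3, 6, 6), bool), (2.5, 2.0, 2.0))
        bins, frac = dvh(dose, mask)
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac[0] == pytest.approx(1.0)


class TestCompareAccumulation:
    def test_coincident_hot_spots_equality(self):
        """Identical distributions and zero field: addition equals DIR."""
        data = np.zeros((4, 10, 10))
        data[2, 4:6, 4:6] = 50.0
        data += 5.0
        a = lk.DoseGrid(data, (10, 5, 5))
        mask = lk.StructureMask("oar", np.ones_like(data, bool), (10, 5, 5))
        f = lk.DeformationField.zero(a.shape, a.spacing)
        tab = compare_accumulation(a, a, f, mask, (0.1, 2.0))
        assert np.allclose(tab["added_gy"], tab["dir_gy"])

    def test_misaligned_hot_spots_addition_overestimates(self):
        base = np.full((4, 10, 10), 5.0)
        e = base.copy(); e[0:2, 1:4, 1:4] = 60.0  # hot regions larger than 2 cm^3
        b = base.copy(); b[2:4, 6:9, 6:9] = 55.0
        ebrt = lk.DoseGrid(e, (10, 5, 5))
        brt = lk.DoseGrid(b, (10, 5, 5))
        mask = lk.StructureMask("oar", np.ones_like(base, bool), (10, 5, 5))
        f = lk.DeformationField.zero(ebrt.shape, ebrt.spacing)
        tab = compare_accumulation(ebrt, brt, f, mask, (0.1, 2.0))
        assert (tab["added_gy"] > tab["dir_gy"]).all()

    def test_matches_hand_sort_on_toy_mask(self, rng):
        e = lk.DoseGrid(rng.uniform(0, 50, (2, 5, 2)), (10, 10, 10))
        b = lk.DoseGrid(rng.uniform(0, 50, (2, 5, 2)), (10, 10, 10))
        mask = lk.StructureMask("oar", np.ones((2, 5, 2), bool), (10, 10, 10))
        f = lk.DeformationField.zero(e.shape, e.spacing)
        tab = compare_accumulation(e, b, f, mask, (2.0,))
        k = 2  # ceil(2 cm3 / 1 cm3)
        added = np.sort(e.data.ravel())[-k] + np.sort(b.data.ravel())[-k]
        dirv = np.sort((e.data + b.data).ravel())[-k]
        row = tab.iloc[0]
        assert row.added_gy == pytest.approx(added)
        assert row.dir_gy == pytest.approx(dirv)
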