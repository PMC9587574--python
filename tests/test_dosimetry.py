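"""Plan normalization, DVH curves/metrics, healthy brain, gamma analysis."""

import numpy as np
import pytest

from segqa import (
    DoseGrid,
    GammaCriteria,
    GridSpec,
    cumulative_dvh,
    dvh_metrics,
    gamma_analysis,
    healthy_brain,
    make_head_phantom,
    normalize_plan,
    synthesize_dose,
)
from segqa.targets import build_ptv


def brute_force_gamma(reference: DoseGrid, evaluated: DoseGrid, criteria: GammaCriteria, factor: int = 3):
    """Exhaustive gamma over every point of the subdivided evaluated grid.

    Independent of the implementation: trilinear interpolation is written out
    per point, and no search-radius truncation is applied.
    """
    grid = reference.grid
    tol = criteria.dose_percent / 100.0 * reference.prescription_gy
    spacing = np.asarray(grid.spacing)
    shape = np.asarray(grid.shape)

    def trilinear(dose, u):
        lo = np.floor(u).astype(int)
        lo = np.clip(lo, 0, shape - 2)
        f = u - lo
        acc = 0.0
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    w = ((1 - f[0]) if di == 0 else f[0]) * \
                        ((1 - f[1]) if dj == 0 else f[1]) * \
                        ((1 - f[2]) if dk == 0 else f[2])
                    acc += w * dose[lo[0] + di, lo[1] + dj, lo[2] + dk]
        return acc

    fine_idx = [np.arange(factor * (n - 1) + 1) / factor for n in shape]
    fine_points = np.array(np.meshgrid(*fine_idx, indexing="ij")).reshape(3, -1).T
    fine_doses = np.array([trilinear(evaluated.dose, u) for u in fine_points])
    fine_mm = fine_points * spacing

    gamma_map = np.full(grid.shape, np.nan)
    for idx in np.argwhere(reference.dose >= criteria.cutoff_gy):
        p = idx * spacing
        d2 = ((fine_mm - p) ** 2).sum(1) / criteria.dta_mm**2
        dd2 = (fine_doses - reference.dose[tuple(idx)]) ** 2 / tol**2
        gamma_map[tuple(idx)] = np.sqrt((d2 + dd2).min())
    return gamma_map


class TestNormalizePlan:
    def test_scaling_to_prescription(self):
        grid = GridSpec((12, 12, 12))
        ptv = grid.empty_mask()
        ptv[4:8, 4:8, 4:8] = True
        dose = DoseGrid(grid, np.full(grid.shape, 30.0), prescription_gy=60.0)
        normed = normalize_plan(dose, ptv)
        assert np.allclose(normed.dose, 60.0)

    def test_idempotent_and_d50_exact(self):
        grid = GridSpec((16, 16, 16))
        ptv = grid.empty_mask()
        ptv[5:11, 5:11, 5:11] = True
        rng = np.random.default_rng(3)
        dose = DoseGrid(grid, rng.uniform(10, 50, grid.shape), 60.0)
        once = normalize_plan(dose, ptv)
        assert np.median(once.dose[ptv]) == pytest.approx(60.0)
        twice = normalize_plan(once, ptv)
        assert np.allclose(once.dose, twice.dose)

    def test_zero_median_rejected(self):
        grid = GridSpec((8, 8, 8))
        ptv = grid.empty_mask()
        ptv[0, 0, 0] = True
        with pytest.raises(ValueError):
            normalize_plan(DoseGrid(grid, np.zeros(grid.shape)), ptv)


class TestDvh:
    def test_uniform_dose_step_curve(self):
        grid = GridSpec((10, 10, 10))
        s = grid.empty_mask()
        s[2:6, 2:6, 2:6] = True
        dose = DoseGrid(grid, np.full(grid.shape, 60.0))
        curve = cumulative_dvh(dose, s)
        assert curve.cumulative_volume_percent[0] == 100.0
        assert all(v == 100.0 for e, v in zip(curve.bin_edges_gy, curve.cumulative_volume_percent) if e <= 60.0)
        assert all(v == 0.0 for e, v in zip(curve.bin_edges_gy, curve.cumulative_volume_percent) if e > 60.0)

    def test_two_level_structure(self):
        grid = GridSpec((10, 10, 2))
        s = np.ones(grid.shape, bool)
        dose = np.full(grid.shape, 20.0)
        dose[..., 1] = 40.0
        curve = cumulative_dvh(DoseGrid(grid, dose), s)
        at_30 = curve.cumulative_volume_percent[np.searchsorted(curve.bin_edges_gy, 30.0)]
        assert at_30 == 50.0

    def test_matches_counting_oracle_on_random_grid(self):
        grid = GridSpec((10, 10, 10))
        rng = np.random.default_rng(12)
        dose = DoseGrid(grid, rng.uniform(0, 70, grid.shape))
        s = rng.random(grid.shape) < 0.5
        curve = cumulative_dvh(dose, s)
        inside = dose.dose[s]
        for edge, vol in zip(curve.bin_edges_gy[::7], curve.cumulative_volume_percent[::7]):
            assert vol == pytest.approx(100.0 * (inside >= edge).mean())

    def test_curve_non_increasing(self):
        grid = GridSpec((8, 8, 8))
        rng = np.random.default_rng(13)
        curve = cumulative_dvh(DoseGrid(grid, rng.uniform(0, 60, grid.shape)), np.ones(grid.shape, bool))
        assert np.all(np.diff(curve.cumulative_volume_percent) <= 0)


class TestDvhMetrics:
    def test_uniform_dose_all_metrics_equal(self):
        grid = GridSpec((12, 12, 12))
        s = grid.empty_mask()
        s[1:11, 1:11, 1:11] = True  # 1000 voxels = 1 cc at 1 mm
        m = dvh_metrics(DoseGrid(grid, np.full(grid.shape, 60.0)), s)
        assert (m.mean_gy, m.min_gy, m.max_gy, m.d95_gy, m.d98_gy, m.d1percent_gy, m.d1cc_gy) == (60.0,) * 7

    def test_staircase_percentiles(self):
        # 101 equal voxels, doses 0..100 Gy
        grid = GridSpec((101, 1, 1))
        dose = DoseGrid(grid, np.arange(101, dtype=float).reshape(101, 1, 1))
        m = dvh_metrics(dose, np.ones(grid.shape, bool))
        assert m.d98_gy == pytest.approx(2.0)
        assert m.d95_gy == pytest.approx(5.0)
        assert m.mean_gy == pytest.approx(50.0)
        assert m.min_gy == 0.0 and m.max_gy == 100.0

    def test_d1cc_counting_oracle(self):
        # 2000 voxels of 1 mm^3, dose = index / 10 Gy
        grid = GridSpec((2000, 1, 1))
        dose = DoseGrid(grid, (np.arange(2000, dtype=float) / 10).reshape(2000, 1, 1), 200.0)
        m = dvh_metrics(dose, np.ones(grid.shape, bool))
        hottest_1000th = np.sort(dose.dose.ravel())[::-1][999]
        assert m.d1cc_gy == pytest.approx(hottest_1000th) == pytest.approx(100.0)

    def test_small_structure_d1cc_flagged(self):
        grid = GridSpec((10, 10, 10))
        s = grid.empty_mask()
        s[4:6, 4:6, 4:6] = True  # 8 mm^3 << 1 cc
        rng = np.random.default_rng(5)
        m = dvh_metrics(DoseGrid(grid, rng.uniform(10, 60, grid.shape)), s)
        assert m.d1cc_warning and m.d1cc_gy == m.min_gy

    def test_permutation_invariance_and_linearity(self):
        grid = GridSpec((9, 9, 9))
        rng = np.random.default_rng(6)
        vals = rng.uniform(0, 60, grid.shape)
        s = rng.random(grid.shape) < 0.6
        m1 = dvh_metrics(DoseGrid(grid, vals), s)
        shuffled = vals.copy().ravel()
        order = rng.permutation(np.flatnonzero(s.ravel()))
        shuffled[np.flatnonzero(s.ravel())] = vals.ravel()[order]
        m2 = dvh_metrics(DoseGrid(grid, shuffled.reshape(grid.shape)), s)
        assert m1.mean_gy == pytest.approx(m2.mean_gy)
        assert m1.d95_gy == pytest.approx(m2.d95_gy)
        m3 = dvh_metrics(DoseGrid(grid, 2.0 * vals), s)
        for a, b in [(m3.mean_gy, m1.mean_gy), (m3.d98_gy, m1.d98_gy), (m3.d1cc_gy, m1.d1cc_gy)]:
            assert a == pytest.approx(2.0 * b)


class TestHealthyBrain:
    def test_set_difference(self, unit_grid):
        rng = np.random.default_rng(2)
        brain = rng.random(unit_grid.shape) < 0.6
        ptv = rng.random(unit_grid.shape) < 0.2
        hb = healthy_brain(brain, ptv, unit_grid)
        assert int(hb.sum()) == int(brain.sum()) - int((brain & ptv).sum())
        assert np.array_equal(healthy_brain(brain, unit_grid.empty_mask(), unit_grid), brain)
        assert not healthy_brain(brain, np.ones(unit_grid.shape, bool), unit_grid).any()


def smooth_random_dose(grid, seed, base=40.0, amp=15.0):
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    noise = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=2.5)
    noise = noise / np.abs(noise).max()
    return DoseGrid(grid, np.clip(base + amp * noise, 0, None), prescription_gy=60.0)


class TestGamma:
    def test_identical_grids_gamma_zero(self):
        grid = GridSpec((12, 12, 12), (2.0, 2.0, 2.0))
        dose = smooth_random_dose(grid, 1)
        res = gamma_analysis(dose, dose)
        assert res.pass_rate_percent == 100.0
        assert np.nanmax(res.gamma_map) == 0.0
        assert res.n_evaluated == int((dose.dose >= 20.0).sum())

    def test_uniform_offset_equals_dose_tolerance(self):
        # spatially uniform fields: distance search cannot compensate, so a
        # 1.8 Gy offset at 60 Gy prescription pins gamma at exactly 1.0
        grid = GridSpec((10, 10, 10), (2.0, 2.0, 2.0))
        ref = DoseGrid(grid, np.full(grid.shape, 40.0), 60.0)
        ev = DoseGrid(grid, np.full(grid.shape, 41.8), 60.0)
        res = gamma_analysis(ref, ev)
        assert np.nanmin(res.gamma_map) == pytest.approx(1.0)
        assert np.nanmax(res.gamma_map) == pytest.approx(1.0)
        assert res.pass_rate_percent == 100.0

    def test_matches_brute_force_oracle(self):
        grid = GridSpec((12, 12, 12), (2.0, 2.0, 2.0))
        ref = smooth_random_dose(grid, 7)
        ev = smooth_random_dose(grid, 8)
        criteria = GammaCriteria()
        res = gamma_analysis(ref, ev, criteria, subdivision=3, search_radius_factor=None)
        oracle = brute_force_gamma(ref, ev, criteria, factor=3)
        assert np.allclose(res.gamma_map, oracle, atol=1e-6, equal_nan=True)

    def test_asymmetric_in_arguments(self):
        grid = GridSpec((12, 12, 12), (2.0, 2.0, 2.0))
        ref = smooth_random_dose(grid, 9)
        ev = smooth_random_dose(grid, 10, base=43.0)
        a = gamma_analysis(ref, ev)
        b = gamma_analysis(ev, ref)
        assert a.pass_rate_percent != b.pass_rate_percent or not np.allclose(
            a.gamma_map, b.gamma_map, equal_nan=True
        )

    def test_pass_rate_monotone_in_criteria(self):
        grid = GridSpec((12, 12, 12), (2.0, 2.0, 2.0))
        ref = smooth_random_dose(grid, 11)
        ev = smooth_random_dose(grid, 12, base=42.5)
        tight = gamma_analysis(ref, ev, GammaCriteria(2.0, 2.0, 20.0)).pass_rate_percent
        loose_dose = gamma_analysis(ref, ev, GammaCriteria(4.0, 2.0, 20.0)).pass_rate_percent
        loose_dta = gamma_analysis(ref, ev, GammaCriteria(2.0, 4.0, 20.0)).pass_rate_percent
        assert loose_dose >= tight and loose_dta >= tight

    def test_no_voxel_above_cutoff_rejected(self):
        grid = GridSpec((8, 8, 8))
        low = DoseGrid(grid, np.full(grid.shape, 5.0))
        with pytest.raises(ValueError, match="cutoff"):
            gamma_analysis(low, low)


class TestOutlierDoseEffect:
    def test_distant_outlier_increases_healthy_brain_dose(self):
        grid = GridSpec((64, 64, 64), (2.0, 2.0, 2.0))
        truth = make_head_phantom(grid, seed=4)
        ref_ptv = build_ptv(truth, 3.0)["PTV"]
        outlier = grid.empty_mask()
        outlier[12:16, 30:34, 30:34] = True  # distant blob inside the brain
        assert not np.logical_and(outlier, ref_ptv).any()
        dose_ref = synthesize_dose(grid, ref_ptv)
        dose_out = synthesize_dose(grid, ref_ptv | outlier)
        hb = healthy_brain(truth["brain"], ref_ptv, grid)
        mean_ref = dvh_metrics(dose_ref, hb).mean_gy
        mean_out = dvh_metrics(dose_out, hb).mean_gy
        assert mean_out > mean_ref
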