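"""Gamma index, DVH metrics, PPD and the FOV density override."""

import numpy as np
import pytest
from scipy import ndimage

from masct.dose_metrics import (
    DVHCurve,
    GammaCriteria,
    cumulative_dvh,
    dvh_point,
    gamma_map,
    gamma_pass_rate,
    override_outside_fov,
    ppd,
)
from masct.errors import UndefinedMetricError, UsageError
from masct.image import BinaryMask, GridSpec, VolumeImage

from conftest import make_grid
from gamma_oracle import gamma_bruteforce


def dose_grid(shape=(20, 20, 20)):
    return GridSpec(shape, (2.5, 2.5, 2.5))


def smooth_dose_pair(seed, shape=(20, 20, 20)):
    """Seeded pair of smooth positive dose fields differing by a few percent
    and a sub-voxel shift."""
    g = dose_grid(shape)
    rng = np.random.default_rng(seed)
    base = ndimage.gaussian_filter(rng.normal(size=shape), 3.0)
    base = 1.0 + 2.0 * (base - base.min()) / (np.ptp(base) + 1e-12)
    bump = ndimage.gaussian_filter(rng.normal(size=shape), 4.0)
    bump /= max(np.abs(bump).max(), 1e-12)
    ev = base * (1.0 + 0.03 * bump)
    ev = ndimage.shift(ev, (0.3, -0.2, 0.1), order=1, mode="nearest")
    return (VolumeImage(base, g, "DOSE"), VolumeImage(np.maximum(ev, 0), g, "DOSE"))


def full_mask(grid):
    return BinaryMask(np.ones(grid.shape, bool), grid)


class TestOverride:
    def test_fov_covering_body_changes_nothing(self, small_grid):
        rng = np.random.default_rng(0)
        ct = VolumeImage(rng.normal(size=small_grid.shape) * 100, small_grid, "CT")
        body = BinaryMask(rng.random(small_grid.shape) > 0.5, small_grid)
        out = override_outside_fov(ct, body, full_mask(small_grid))
        np.testing.assert_array_equal(out.values, ct.values)

    def test_body_ring_outside_fov_becomes_water(self, small_grid):
        ct = VolumeImage(np.full(small_grid.shape, 500.0), small_grid, "CT")
        body = full_mask(small_grid)
        fov = np.zeros(small_grid.shape, bool)
        fov[:, :, :10] = True
        out = override_outside_fov(ct, body, BinaryMask(fov, small_grid))
        assert np.all(out.values[:, :, :10] == 500.0)
        assert np.all(out.values[:, :, 10:] == 0.0)

    def test_missing_tissue_air_takes_precedence(self, small_grid):
        ct = VolumeImage(np.full(small_grid.shape, 500.0), small_grid, "CT")
        body = full_mask(small_grid)
        fov = BinaryMask(np.zeros(small_grid.shape, bool), small_grid)
        missing = np.zeros(small_grid.shape, bool)
        missing[0, 0, 0] = True
        out = override_outside_fov(ct, body, fov, BinaryMask(missing, small_grid))
        assert out.values[0, 0, 0] == -1000.0  # air wins over water
        assert out.values[1, 1, 1] == 0.0


class TestGamma:
    def test_identical_doses_gamma_zero(self):
        ref, _ = smooth_dose_pair(1)
        gm = gamma_map(ref, ref, GammaCriteria(3, 3, "local"), full_mask(ref.grid))
        assert np.nanmax(gm.values) == 0.0
        assert gamma_pass_rate(gm) == 100.0

    def test_uniform_three_percent_offset_gives_gamma_one(self):
        g = dose_grid((12, 12, 12))
        ref = VolumeImage(np.full(g.shape, 2.0), g, "DOSE")
        ev = VolumeImage(np.full(g.shape, 2.06), g, "DOSE")
        gm = gamma_map(ref, ev, GammaCriteria(3, 3, "local"), full_mask(g))
        np.testing.assert_allclose(gm.values[gm.defined], 1.0, atol=1e-6)

    def test_matches_bruteforce_oracle(self):
        ref, ev = smooth_dose_pair(2)
        crit = GammaCriteria(2, 2, "local")
        gm = gamma_map(ref, ev, crit, full_mask(ref.grid))
        oracle, defined = gamma_bruteforce(ref, ev, crit, full_mask(ref.grid))
        np.testing.assert_array_equal(gm.defined, defined)
        assert np.abs(gm.values[defined] - oracle[defined]).max() <= 0.02

    def test_asymmetric_in_arguments(self):
        ref, ev = smooth_dose_pair(3)
        crit = GammaCriteria(2, 2, "local")
        a = gamma_map(ref, ev, crit, full_mask(ref.grid))
        b = gamma_map(ev, ref, crit, full_mask(ref.grid))
        common = a.defined & b.defined
        assert np.abs(a.values[common] - b.values[common]).max() > 1e-6

    def test_criteria_monotonicity_per_voxel(self):
        ref, ev = smooth_dose_pair(4)
        m = full_mask(ref.grid)
        tight = gamma_map(ref, ev, GammaCriteria(2, 2, "local"), m)
        loose = gamma_map(ref, ev, GammaCriteria(3, 3, "local"), m)
        common = tight.defined & loose.defined
        # continuous gamma is exactly monotone under loosened criteria; the
        # discrete candidate lattices scale with DTA, so allow their
        # resolution difference
        assert np.all(loose.values[common] <= tight.values[common] + 0.1)
        assert gamma_pass_rate(loose, m) >= gamma_pass_rate(tight, m)

    def test_negative_dose_rejected(self):
        g = dose_grid((8, 8, 8))
        bad = VolumeImage(np.full(g.shape, -1.0), g, "DOSE")
        ok = VolumeImage(np.ones(g.shape), g, "DOSE")
        with pytest.raises(UsageError):
            gamma_map(bad, ok, GammaCriteria(3, 3, "local"), full_mask(g))

    def test_all_voxels_below_floor_rejected(self):
        g = dose_grid((8, 8, 8))
        ref = VolumeImage(np.zeros(g.shape), g, "DOSE")
        with pytest.raises(UndefinedMetricError):
            gamma_map(ref, ref, GammaCriteria(3, 3, "local"), full_mask(g))


class TestPassRate:
    def _gmap(self, grid, values):
        from masct.dose_metrics import GammaMap

        return GammaMap(values, np.isfinite(values), GammaCriteria(3, 3, "local"),
                        grid)

    def test_all_zero_is_hundred(self, small_grid):
        gm = self._gmap(small_grid, np.zeros(small_grid.shape))
        assert gamma_pass_rate(gm) == 100.0

    def test_all_above_one_is_zero(self, small_grid):
        gm = self._gmap(small_grid, np.full(small_grid.shape, 1.5))
        assert gamma_pass_rate(gm) == 0.0

    def test_half_half_counting(self, small_grid):
        vals = np.full(small_grid.shape, 0.5)
        vals[:8] = 2.0  # half the 16^3 lattice
        gm = self._gmap(small_grid, vals)
        assert gamma_pass_rate(gm) == 50.0


class TestDVH:
    def test_uniform_dose_step_function(self, small_grid):
        d = VolumeImage(np.full(small_grid.shape, 10.0), small_grid, "DOSE")
        s = full_mask(small_grid)
        curve = cumulative_dvh(d, s)
        assert curve.at(0.0) == 1.0
        assert curve.at(9.99) == 1.0
        assert curve.at(10.01) == 0.0

    def test_two_level_dose_half_volume(self, small_grid):
        vals = np.full(small_grid.shape, 1.0)
        vals[:8] = 3.0
        d = VolumeImage(vals, small_grid, "DOSE")
        curve = cumulative_dvh(d, full_mask(small_grid))
        assert curve.at(2.0) == pytest.approx(0.5)

    def test_monotone_non_increasing(self, small_grid):
        rng = np.random.default_rng(6)
        d = VolumeImage(rng.uniform(0, 70, small_grid.shape), small_grid, "DOSE")
        curve = cumulative_dvh(d, full_mask(small_grid))
        assert np.all(np.diff(curve.volume_fraction) <= 1e-12)
        assert curve.volume_fraction[0] == 1.0

    def test_uniform_dose_points_coincide(self, small_grid):
        d = VolumeImage(np.full(small_grid.shape, 42.0), small_grid, "DOSE")
        s = full_mask(small_grid)
        for m in ("D98", "Dmean", "D2"):
            assert dvh_point(d, s, m) == pytest.approx(42.0)

    def test_linear_doses_match_percentile_oracle(self):
        g = make_grid((100, 1, 1))
        d = VolumeImage(np.arange(1.0, 101.0).reshape(100, 1, 1), g, "DOSE")
        s = full_mask(g)
        assert dvh_point(d, s, "Dmean") == pytest.approx(50.5)
        # oracle: sorted linear-interpolated percentiles of 1..100
        assert dvh_point(d, s, "D2") == pytest.approx(1 + 0.98 * 99)   # 98.02
        assert dvh_point(d, s, "D98") == pytest.approx(1 + 0.02 * 99)  # 2.98

    def test_ordering_invariant(self, small_grid):
        rng = np.random.default_rng(7)
        d = VolumeImage(rng.uniform(0, 70, small_grid.shape), small_grid, "DOSE")
        s = BinaryMask(rng.random(small_grid.shape) > 0.3, small_grid)
        d98 = dvh_point(d, s, "D98")
        dmean = dvh_point(d, s, "Dmean")
        d2 = dvh_point(d, s, "D2")
        assert d98 <= dmean <= d2

    def test_empty_structure_rejected(self, small_grid):
        d = VolumeImage(np.ones(small_grid.shape), small_grid, "DOSE")
        empty = BinaryMask(np.zeros(small_grid.shape, bool), small_grid)
        with pytest.raises(UndefinedMetricError):
            cumulative_dvh(d, empty)


class TestPPD:
    def test_equal_values_zero(self):
        assert ppd(65.0, 65.0) == 0.0

    def test_lower_evaluated_positive(self):
        assert ppd(65.0, 64.35) == pytest.approx(1.0)

    def test_higher_evaluated_negative(self):
        assert ppd(65.0, 66.3) == pytest.approx(-2.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(UndefinedMetricError):
            ppd(0.0, 1.0)
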