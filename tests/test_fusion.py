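"""Local similarity, spatial weighting, fusion and the synthesis loop."""

import numpy as np
import pytest

from masct.errors import UsageError
from masct.fusion import (
    SimilarityMap,
    fuse,
    lncc_map,
    load_database,
    map_to_ct_space,
    refine,
    save_database,
    synthesize,
    weights_from_similarity,
)
from masct.geometry_metrics import mae
from masct.image import BinaryMask, VolumeImage, extract_body_mask

from conftest import make_grid


def _gaussian_kernel_1d(sigma_vox, truncate=4.0):
    radius = int(truncate * sigma_vox + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma_vox) ** 2)
    return k / k.sum(), radius


def lncc_bruteforce(t, a, sigma_mm, spacing):
    """Windowed-Pearson oracle with explicit 3-D window sums (no separable
    filtering): for every voxel, gather the truncated Gaussian window, keep
    in-domain voxels, and compute the weighted correlation directly."""
    kernels = []
    radii = []
    for s in spacing:
        k, r = _gaussian_kernel_1d(sigma_mm / s)
        kernels.append(k)
        radii.append(r)
    w3 = (
        kernels[0][:, None, None]
        * kernels[1][None, :, None]
        * kernels[2][None, None, :]
    )
    out = np.zeros(t.shape)
    shape = t.shape
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                sl = []
                wl = []
                for ax, (c, r, n) in enumerate(zip((i, j, k), radii, shape)):
                    lo, hi = max(0, c - r), min(n, c + r + 1)
                    sl.append(slice(lo, hi))
                    wl.append(slice(lo - (c - r), hi - (c - r)))
                w = w3[wl[0], wl[1], wl[2]]
                tv = t[sl[0], sl[1], sl[2]]
                av = a[sl[0], sl[1], sl[2]]
                wsum = w.sum()
                mt = (w * tv).sum() / wsum
                ma = (w * av).sum() / wsum
                vt = (w * (tv - mt) ** 2).sum() / wsum
                va = (w * (av - ma) ** 2).sum() / wsum
                cov = (w * (tv - mt) * (av - ma)).sum() / wsum
                denom = np.sqrt(vt * va)
                out[i, j, k] = cov / denom if denom > 0 else 0.0
    return out


class TestLNCC:
    def test_self_correlation_is_one(self, small_grid):
        rng = np.random.default_rng(0)
        vol = VolumeImage(rng.normal(size=small_grid.shape), small_grid, "MR")
        s = lncc_map(vol, vol, 3.0)
        assert np.all(s.values[s.defined] > 1 - 1e-6)

    def test_anticorrelation_is_minus_one(self, small_grid):
        rng = np.random.default_rng(1)
        vol = VolumeImage(rng.normal(size=small_grid.shape), small_grid, "MR")
        neg = vol.with_values(-vol.values)
        s = lncc_map(vol, neg, 3.0)
        assert np.all(s.values[s.defined] < -1 + 1e-6)

    def test_matches_bruteforce_windowed_pearson(self, small_grid):
        rng = np.random.default_rng(2)
        t = VolumeImage(rng.normal(size=small_grid.shape), small_grid, "MR")
        a = VolumeImage(
            0.5 * t.values + rng.normal(size=small_grid.shape), small_grid, "MR"
        )
        s = lncc_map(t, a, 3.0)
        oracle = lncc_bruteforce(t.values, a.values, 3.0, small_grid.spacing)
        np.testing.assert_allclose(s.values[s.defined], oracle[s.defined],
                                   atol=1e-5)

    def test_constant_region_undefined(self, small_grid):
        flat = VolumeImage(np.zeros(small_grid.shape), small_grid, "MR")
        rng = np.random.default_rng(3)
        other = VolumeImage(rng.normal(size=small_grid.shape), small_grid, "MR")
        s = lncc_map(flat, other, 3.0)
        assert not s.defined.any()
        assert np.all(s.values == 0.0)


class TestWeights:
    def _sims(self, grid, arrays):
        return [
            SimilarityMap(np.asarray(a, dtype=float), np.ones(grid.shape, bool),
                          f"a{i}", 3.0)
            for i, a in enumerate(arrays)
        ]

    def test_beta_zero_uniform(self, small_grid):
        rng = np.random.default_rng(4)
        sims = self._sims(small_grid, rng.random((3,) + small_grid.shape))
        w = weights_from_similarity(sims, beta=0.0, top_k=3)
        for wi in w.weights:
            np.testing.assert_allclose(wi, 1 / 3, atol=1e-12)

    def test_winner_take_all(self, small_grid):
        rng = np.random.default_rng(5)
        arrays = rng.random((3,) + small_grid.shape)
        sims = self._sims(small_grid, arrays)
        w = weights_from_similarity(sims, beta=1.0, top_k=1)
        best = np.argmax(arrays, axis=0)
        for j, wj in enumerate(w.weights):
            np.testing.assert_array_equal(wj == 1.0, best == j)

    def test_rank_softmax_hand_computed(self):
        g = make_grid((1, 1, 1))
        sims = self._sims(g, [[[[0.9]]], [[[0.5]]], [[[0.1]]]])
        w = weights_from_similarity(sims, beta=1.0, top_k=3)
        got = [float(wj[0, 0, 0]) for wj in w.weights]
        # oracle: softmax over ranks 0,1,2
        expected = np.exp(-np.arange(3.0))
        expected /= expected.sum()
        np.testing.assert_allclose(got, expected, atol=1e-3)
        np.testing.assert_allclose(got, [0.6652, 0.2447, 0.0900], atol=1e-3)

    def test_weights_sum_to_one_on_mask(self, small_grid):
        rng = np.random.default_rng(6)
        sims = self._sims(small_grid, rng.random((5,) + small_grid.shape))
        w = weights_from_similarity(sims, beta=0.7, top_k=3)
        total = np.sum(w.weights, axis=0)
        np.testing.assert_allclose(total[w.normalization_mask], 1.0, atol=1e-6)
        assert all((wj >= 0).all() for wj in w.weights)


class TestFuse:
    def test_identical_inputs_fixed_point(self, small_grid):
        rng = np.random.default_rng(7)
        ct = VolumeImage(rng.normal(size=small_grid.shape) * 500, small_grid, "CT")
        sims = [
            SimilarityMap(rng.random(small_grid.shape),
                          np.ones(small_grid.shape, bool), f"a{i}", 3.0)
            for i in range(4)
        ]
        w = weights_from_similarity(sims, beta=0.5)
        out = fuse([ct] * 4, w)
        np.testing.assert_allclose(out.values, ct.values, atol=1e-9)

    def test_degenerate_weight_selects_single_atlas(self, small_grid):
        a = VolumeImage(np.zeros(small_grid.shape), small_grid, "CT")
        b = VolumeImage(np.full(small_grid.shape, 1000.0), small_grid, "CT")
        sims = [
            SimilarityMap(np.full(small_grid.shape, v),
                          np.ones(small_grid.shape, bool), n, 3.0)
            for v, n in ((0.9, "a"), (0.1, "b"))
        ]
        w = weights_from_similarity(sims, beta=1.0, top_k=1)
        out = fuse([a, b], w)
        np.testing.assert_array_equal(out.values, a.values)

    def test_uniform_average_of_constants(self, small_grid):
        a = VolumeImage(np.zeros(small_grid.shape), small_grid, "CT")
        b = VolumeImage(np.full(small_grid.shape, 1000.0), small_grid, "CT")
        sims = [
            SimilarityMap(np.full(small_grid.shape, 0.5),
                          np.ones(small_grid.shape, bool), n, 3.0)
            for n in ("a", "b")
        ]
        w = weights_from_similarity(sims, beta=0.0)
        out = fuse([a, b], w)
        np.testing.assert_allclose(out.values, 500.0, atol=1e-9)

    def test_count_mismatch_rejected(self, small_grid):
        a = VolumeImage(np.zeros(small_grid.shape), small_grid, "CT")
        sims = [
            SimilarityMap(np.full(small_grid.shape, 0.5),
                          np.ones(small_grid.shape, bool), "a", 3.0)
        ]
        w = weights_from_similarity(sims)
        with pytest.raises(UsageError):
            fuse([a, a], w)

    def test_permutation_invariance_bit_for_bit(self, small_grid):
        rng = np.random.default_rng(8)
        cts = [
            VolumeImage(rng.normal(size=small_grid.shape) * 300, small_grid, "CT")
            for _ in range(4)
        ]
        simvals = [rng.random(small_grid.shape) for _ in range(4)]
        ones = np.ones(small_grid.shape, bool)

        def build(order):
            sims = [SimilarityMap(simvals[i], ones, f"a{i}", 3.0) for i in order]
            w = weights_from_similarity(sims, beta=0.5)
            return fuse([cts[i] for i in order], w)

        ref = build([0, 1, 2, 3])
        perm = build([2, 0, 3, 1])
        np.testing.assert_array_equal(ref.values, perm.values)

    def test_convexity_bounds(self, small_grid):
        rng = np.random.default_rng(9)
        cts = [
            VolumeImage(rng.normal(size=small_grid.shape) * 300, small_grid, "CT")
            for _ in range(5)
        ]
        sims = [
            SimilarityMap(rng.random(small_grid.shape),
                          np.ones(small_grid.shape, bool), f"a{i}", 3.0)
            for i in range(5)
        ]
        w = weights_from_similarity(sims, beta=0.8, top_k=3)
        out = fuse(cts, w)
        stack = np.stack([c.values for c in cts])
        assert np.all(out.values >= stack.min(0) - 1e-6)
        assert np.all(out.values <= stack.max(0) + 1e-6)


class TestSynthesis:
    def test_refine_requires_positive_iterations(self, perfect_atlas_run):
        run = perfect_atlas_run
        with pytest.raises(UsageError):
            refine(run["result0"], run["subject"].mr_channels, run["db"], 0)

    def test_small_database_rejected(self, perfect_atlas_run):
        run = perfect_atlas_run
        db = run["db"]
        from masct.fusion import AtlasDatabase

        tiny = AtlasDatabase(db.atlases[:1], db.channel_names)
        with pytest.raises(UsageError):
            synthesize(run["subject"].mr_channels, tiny)

    def test_fusion_beats_best_single_atlas(self, loo_run):
        subject = loo_run["subject"]
        body = extract_body_mask(subject.ct, "CT")
        result = loo_run["result0"]
        fused_mae = mae(subject.ct, result.sct, body)
        singles = [mae(subject.ct, m, body) for m in result.mapped_cts]
        assert fused_mae < min(singles)

    def test_dropping_least_similar_atlas_is_robust(self, loo_run):
        from masct.fusion import lncc_map as _lncc, weights_from_similarity as _w

        subject = loo_run["subject"]
        cfg = loo_run["config"]
        result = loo_run["result0"]
        body = extract_body_mask(subject.ct, "CT")
        n = len(result.mapped_cts)
        sims = [
            _lncc(subject.mr_channels[0], mrs[0], cfg.sigma_mm)
            for mrs in result.mapped_mrs
        ]
        full = fuse(result.mapped_cts, _w(sims, cfg.beta, top_k=n))
        reduced = fuse(result.mapped_cts, _w(sims, cfg.beta, top_k=n - 1))
        assert abs(
            mae(subject.ct, reduced, body) - mae(subject.ct, full, body)
        ) <= 5.0

    def test_map_to_ct_space_identity_is_resample(self, perfect_atlas_run):
        run = perfect_atlas_run
        out = map_to_ct_space(run["result0"], None, run["subject"].ct.grid)
        np.testing.assert_allclose(out.values, run["result0"].sct.values,
                                   atol=1e-9)


def test_database_manifest_roundtrip(tmp_path, perfect_atlas_run):
    db = perfect_atlas_run["db"]
    manifest = save_database(db, tmp_path / "db")
    back = load_database(manifest)
    assert back.channel_names == db.channel_names
    assert [a.id for a in back.atlases] == [a.id for a in db.atlases]
    np.testing.assert_allclose(
        back.atlases[0].ct.values, db.atlases[0].ct.values, atol=1e-12
    )
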