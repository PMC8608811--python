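import numpy as np
import pytest
from scipy import stats

import _oracles
from intpipe.mapping import RoiMask, extract_clusters, roi_mean, voxelwise_ttest
from intpipe.timescale import IntMap


def _maps_from_stack(stack, mask, tr=2.0, affine=None):
    return [
        IntMap(grid=np.where(mask, grid, np.nan), mask=mask, tr=tr,
               affine=np.eye(4) if affine is None else affine)
        for grid in stack
    ]


@pytest.fixture
def random_groups(rng):
    mask = np.ones((6, 6, 6), dtype=bool)
    a = rng.normal(1.0, 0.3, size=(8, 6, 6, 6))
    b = rng.normal(1.0, 0.3, size=(7, 6, 6, 6))
    return _maps_from_stack(a, mask), _maps_from_stack(b, mask), mask


class TestVoxelwiseTtest:
    def test_single_voxel_matches_scalar_test(self, random_groups, rng):
        maps_a, maps_b, mask = random_groups
        stat = voxelwise_ttest(maps_a, maps_b, variant="pooled")
        coords = np.argwhere(mask)
        for idx in rng.choice(len(coords), size=10, replace=False):
            i, j, k = coords[idx]
            a = np.array([m.grid[i, j, k] for m in maps_a])
            b = np.array([m.grid[i, j, k] for m in maps_b])
            t, df = _oracles.pooled_t(a, b)
            assert stat.t[i, j, k] == pytest.approx(t, abs=1e-10)
            assert stat.p[i, j, k] == pytest.approx(
                _oracles.t_pvalue(t, df), rel=1e-9
            )

    def test_welch_variant_matches_oracle(self, random_groups, rng):
        maps_a, maps_b, mask = random_groups
        stat = voxelwise_ttest(maps_a, maps_b, variant="welch")
        i, j, k = 2, 3, 4
        a = np.array([m.grid[i, j, k] for m in maps_a])
        b = np.array([m.grid[i, j, k] for m in maps_b])
        t, df = _oracles.welch_t(a, b)
        assert stat.t[i, j, k] == pytest.approx(t, abs=1e-10)
        assert stat.df[i, j, k] == pytest.approx(df, rel=1e-9)

    def test_swapping_groups_negates_t(self, random_groups):
        maps_a, maps_b, mask = random_groups
        ab = voxelwise_ttest(maps_a, maps_b)
        ba = voxelwise_ttest(maps_b, maps_a)
        np.testing.assert_allclose(ab.t[mask], -ba.t[mask])
        np.testing.assert_allclose(ab.p[mask], ba.p[mask])

    def test_permuting_within_groups_is_invariant(self, random_groups):
        # identical up to summation order in the mean/variance accumulators
        maps_a, maps_b, _ = random_groups
        base = voxelwise_ttest(maps_a, maps_b)
        perm = voxelwise_ttest(maps_a[::-1], maps_b[::-1])
        np.testing.assert_allclose(base.t, perm.t, rtol=1e-10)

    def test_null_calibration(self, rng):
        mask = np.ones((18, 18, 18), dtype=bool)  # 5832 voxels
        a = _maps_from_stack(rng.normal(size=(10, 18, 18, 18)), mask)
        b = _maps_from_stack(rng.normal(size=(10, 18, 18, 18)), mask)
        stat = voxelwise_ttest(a, b)
        frac = float((stat.p[mask] < 0.001).mean())
        assert frac < 0.004  # ~0.1% expected

    def test_rejects_too_few_maps(self, random_groups):
        maps_a, maps_b, _ = random_groups
        with pytest.raises(ValueError, match="2 maps"):
            voxelwise_ttest(maps_a[:1], maps_b)

    def test_rejects_grid_mismatch(self, random_groups, rng):
        maps_a, maps_b, _ = random_groups
        other = _maps_from_stack(rng.normal(size=(2, 5, 5, 5)), np.ones((5, 5, 5), bool))
        with pytest.raises(ValueError, match="grid"):
            voxelwise_ttest(maps_a, other)


def _stat_from_t(t_grid, mask, df=20, affine=None):
    from intpipe.mapping import StatMap

    p = np.full(mask.shape, np.nan)
    p[mask] = 2 * stats.t.sf(np.abs(t_grid[mask]), df)
    return StatMap(t=t_grid, p=p, df=float(df), mask=mask,
                   affine=np.eye(4) if affine is None else affine)


class TestExtractClusters:
    def test_subthreshold_map_gives_empty_list(self, rng):
        mask = np.ones((8, 8, 8), dtype=bool)
        t = rng.normal(0, 0.5, size=(8, 8, 8))
        records, rois, labels = extract_clusters(_stat_from_t(t, mask))
        assert records == [] and rois == []
        assert not labels.any()

    def test_two_planted_blobs(self):
        mask = np.ones((16, 16, 16), dtype=bool)
        t = np.zeros((16, 16, 16))
        t[1:6, 1:4, 1:3] = 8.0  # 30 voxels
        t[10:13, 10:12, 10:12] = 7.0  # 12 voxels
        records, rois, _ = extract_clusters(
            _stat_from_t(t, mask), min_cluster_size=5
        )
        assert [r.size for r in records] == [30, 12]

    def test_singleton_peak_through_affine(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        t = np.zeros((5, 5, 5))
        t[2, 3, 4] = 9.0
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = [-10.0, -20.0, -30.0]
        records, _, _ = extract_clusters(
            _stat_from_t(t, mask, affine=affine), min_cluster_size=1
        )
        assert len(records) == 1
        assert records[0].size == 1
        assert records[0].peak_mm == (2 * 3 - 10.0, 3 * 3 - 20.0, 4 * 3 - 30.0)
        assert records[0].peak_t == pytest.approx(9.0)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labels_match_flood_fill_oracle(self, connectivity, rng):
        for trial in range(20):
            mask = np.ones((16, 16, 16), dtype=bool)
            t = np.where(rng.random((16, 16, 16)) < 0.08, 8.0, 0.0)
            records, rois, _ = extract_clusters(
                _stat_from_t(t, mask),
                connectivity=connectivity,
                min_cluster_size=1,
            )
            oracle = _oracles.connected_components(t > 0, connectivity)
            got = sorted(
                sorted(map(tuple, np.argwhere(r.voxels).tolist())) for r in rois
            )
            want = sorted(sorted(c) for c in oracle)
            assert got == want

    def test_direction_selects_sign(self):
        mask = np.ones((6, 6, 6), dtype=bool)
        t = np.zeros((6, 6, 6))
        t[0:2, 0:2, 0:2] = 8.0
        t[4:6, 4:6, 4:6] = -8.0
        stat = _stat_from_t(t, mask)
        pos, _, _ = extract_clusters(stat, direction="a_gt_b", min_cluster_size=1)
        neg, _, _ = extract_clusters(stat, direction="b_gt_a", min_cluster_size=1)
        assert len(pos) == 1 and pos[0].peak_t > 0
        assert len(neg) == 1 and neg[0].peak_t < 0

    def test_deterministic_sorting(self, rng):
        mask = np.ones((12, 12, 12), dtype=bool)
        t = np.where(rng.random((12, 12, 12)) < 0.1, 8.0, 0.0)
        stat = _stat_from_t(t, mask)
        first, _, labels1 = extract_clusters(stat, min_cluster_size=1)
        second, _, labels2 = extract_clusters(stat, min_cluster_size=1)
        assert first == second
        np.testing.assert_array_equal(labels1, labels2)
        sizes = [r.size for r in first]
        assert sizes == sorted(sizes, reverse=True)

    def test_fdr_q_at_peak_matches_bh(self, rng):
        mask = np.ones((8, 8, 8), dtype=bool)
        t = rng.normal(size=(8, 8, 8))
        t[1, 1, 1] = 12.0
        stat = _stat_from_t(t, mask)
        records, _, _ = extract_clusters(stat, min_cluster_size=1)
        # brute-force BH: q_i = min over j with p_j >= p_i of p_j * n / rank_j
        p = np.sort(stat.p[mask])
        n = p.size
        q = np.minimum.accumulate((p * n / np.arange(1, n + 1))[::-1])[::-1]
        peak = records[0]
        p_peak = stat.p[peak.peak_ijk]
        assert peak.fdr_q_at_peak == pytest.approx(q[np.searchsorted(p, p_peak)], rel=1e-9)


class TestRoiMean:
    def test_constant_map(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        im = IntMap(grid=np.full((4, 4, 4), 2.5), mask=mask, tr=2.0)
        roi = RoiMask("r", mask.copy())
        assert roi_mean(im, roi) == 2.5

    def test_single_voxel_roi(self, rng):
        mask = np.ones((4, 4, 4), dtype=bool)
        grid = rng.normal(size=(4, 4, 4))
        vox = np.zeros((4, 4, 4), dtype=bool)
        vox[1, 2, 3] = True
        assert roi_mean(IntMap(grid, mask, 2.0), RoiMask("v", vox)) == grid[1, 2, 3]

    def test_matches_sum_over_count(self, rng):
        mask = np.ones((5, 5, 5), dtype=bool)
        grid = rng.normal(size=(5, 5, 5))
        vox = rng.random((5, 5, 5)) < 0.3
        vox[0, 0, 0] = True
        got = roi_mean(IntMap(grid, mask, 2.0), RoiMask("r", vox))
        assert got == pytest.approx(grid[vox].sum() / vox.sum(), rel=1e-12)

    def test_rejects_empty_intersection(self, rng):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[:2] = True
        grid = np.where(mask, 1.0, np.nan)
        vox = np.zeros((4, 4, 4), dtype=bool)
        vox[3, 3, 3] = True
        with pytest.raises(ValueError, match="intersect"):
            roi_mean(IntMap(grid, mask, 2.0), RoiMask("r", vox))
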