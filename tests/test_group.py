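"""Group inference: t-maps, clustering, sign-flip calibration, dual criterion."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nirstroop.geometry import VolumeGrid
from nirstroop.group import (FprTable, VolumeMap, channelwise_t,
                             dual_criterion, group_t_map, overlap_fraction,
                             signflip_mc, threshold_and_cluster)


def toy_grid(shape=(3, 3, 3)):
    return VolumeGrid(origin=np.zeros(3), voxel_size=4.0, shape=shape,
                      mask=np.ones(shape, bool))


class TestGroupTMap:
    def test_df_is_n_minus_one(self, rng):
        grid = toy_grid()
        tmap = group_t_map(rng.standard_normal((31, 27)), grid)
        assert tmap.df == 30

    def test_zero_variance_voxel_masked_nan(self):
        grid = toy_grid()
        X = np.ones((5, 27))  # identical nonzero volumes
        tmap = group_t_map(X, grid)
        assert np.isnan(tmap.values).all()

    def test_mean_t_tracks_noncentrality(self):
        # subjects ~ N(0.5, 1), n=31: mean t across seeds ~= 0.5*sqrt(31)
        grid = toy_grid()
        tvals = []
        for seed in range(60):
            r = np.random.default_rng(seed)
            X = 0.5 + r.standard_normal((31, 27))
            tvals.append(group_t_map(X, grid).values.mean())
        expected = 0.5 * np.sqrt(31)
        assert abs(np.mean(tvals) - expected) < 0.15

    def test_single_subject_rejected(self, rng):
        with pytest.raises(ValueError):
            group_t_map(rng.standard_normal((1, 27)), toy_grid())


class TestThresholdAndCluster:
    def _tmap_from_mask(self, supra_mask, df=30):
        grid = toy_grid(supra_mask.shape)
        values = np.where(supra_mask.ravel(), 10.0, 0.0)
        return VolumeMap(grid=grid, values=values, df=df)

    def test_no_suprathreshold_empty_table(self, rng):
        grid = toy_grid()
        tmap = VolumeMap(grid=grid, values=np.zeros(27), df=30)
        table = threshold_and_cluster(tmap, p_thresh=0.001)
        assert len(table) == 0

    def test_connectivity_splits_diagonal_components(self):
        # two blobs of 5 and 3 voxels touching only diagonally: separate
        # under 6-connectivity, merged under 26-connectivity
        supra = np.zeros((5, 5, 5), bool)
        supra[0, 0, 0:5] = True              # 5-voxel line
        supra[1, 1, 5 - 1:5] = False
        supra[1, 1, 0] = False
        supra[1, 1, 1] = False
        # 3-voxel line sharing only a diagonal corner with the first
        supra[1, 1, 5 - 1] = False
        supra[1, 1, 2:5] = True
        tmap = self._tmap_from_mask(supra)
        t6 = threshold_and_cluster(tmap, p_thresh=0.001, connectivity=6)
        assert sorted(t6.clusters["size"]) == [3, 5]
        t26 = threshold_and_cluster(tmap, p_thresh=0.001, connectivity=26)
        assert list(t26.clusters["size"]) == [8]

    def test_cluster_peak_inside_cluster(self, rng):
        grid = toy_grid((6, 6, 6))
        values = rng.standard_normal(216)
        values[:30] += 5.0
        tmap = VolumeMap(grid=grid, values=values, df=30)
        table, labels = threshold_and_cluster(tmap, p_thresh=0.01,
                                              return_labels=True)
        centers = grid.voxel_centers().reshape(grid.shape + (3,))
        for _, row in table.clusters.iterrows():
            members = labels == row["cluster"]
            peak = np.array([row["peak_x"], row["peak_y"], row["peak_z"]])
            member_xyz = centers[members].reshape(-1, 3)
            assert (np.linalg.norm(member_xyz - peak, axis=1) < 1e-9).any()

    def test_default_significance_is_70_voxels_at_p001(self, rng):
        grid = toy_grid((10, 10, 10))
        values = np.zeros(1000)
        values[:100] = 10.0  # one 100-voxel block (raveled order is connected)
        tmap = VolumeMap(grid=grid, values=values, df=30)
        table = threshold_and_cluster(tmap)
        assert table.p_threshold == 0.001
        assert table.cluster_extent == 70
        assert table.clusters["significant"].iloc[0]

    def test_invalid_threshold_rejected(self):
        tmap = VolumeMap(grid=toy_grid(), values=np.zeros(27), df=30)
        with pytest.raises(ValueError):
            threshold_and_cluster(tmap, p_thresh=1.5)


class TestSignFlip:
    def test_exhaustive_matches_monte_carlo(self, rng):
        # n=4 subjects on a 3x3x3 grid: MC within 3 binomial SE of the
        # exact enumeration over all 16 sign assignments
        grid = toy_grid()
        X = rng.standard_normal((4, 27))
        sizes = (1, 3)
        ps = (0.05, 0.01)
        exact = signflip_mc(X, grid, cluster_sizes=sizes, p_thresholds=ps,
                            exhaustive=True)
        assert exact.n_permutations == 16
        mc = signflip_mc(X, grid, n_perm=800, cluster_sizes=sizes,
                         p_thresholds=ps, seed=5)
        se = np.sqrt(exact.rates * (1 - exact.rates) / 800)
        assert np.all(np.abs(mc.rates - exact.rates) <= 3 * se + 1e-12)

    def test_rates_monotone_in_size_and_threshold(self, rng):
        grid = toy_grid((4, 4, 4))
        X = rng.standard_normal((8, 64))
        tab = signflip_mc(X, grid, n_perm=300, seed=2)
        eps = 0.02  # Monte Carlo slack
        assert np.all(np.diff(tab.rates, axis=0) <= eps)   # larger clusters
        assert np.all(np.diff(tab.rates, axis=1) <= eps)   # stricter p

    def test_permutation_t_distribution_symmetric(self, rng):
        # sign-flipped group means average out to zero at every voxel
        X = rng.standard_normal((10, 27)) + 0.8  # even with a true offset
        signs = np.random.default_rng(3).choice([-1.0, 1.0], size=(2000, 10))
        perm_means = signs @ X / 10
        assert np.abs(perm_means.mean(axis=0)).max() < 0.1

    def test_seed_reproducibility(self, rng):
        grid = toy_grid()
        X = rng.standard_normal((6, 27))
        a = signflip_mc(X, grid, n_perm=100, seed=9)
        b = signflip_mc(X, grid, n_perm=100, seed=9)
        np.testing.assert_array_equal(a.rates, b.rates)

    def test_cell_lookup_and_frame(self, rng):
        grid = toy_grid()
        tab = signflip_mc(rng.standard_normal((5, 27)), grid, n_perm=50,
                          seed=1)
        frame = tab.to_frame()
        assert frame.shape == (4, 4)
        assert tab.cell(70, 0.001) == frame.loc[70, 0.001]


class TestChannelwise:
    def test_null_contrasts_rarely_flagged(self, rng):
        stats_df = channelwise_t(rng.standard_normal((20, 98)))
        assert stats_df["flagged"].mean() < 0.15

    def test_zero_contrast_no_flags(self):
        stats_df = channelwise_t(np.zeros((10, 8)))
        assert not stats_df["flagged"].any()

    def test_power_matches_noncentral_t(self):
        # effect 0.5 sigma, n=31: empirical one-tailed power at p<.05 vs
        # the noncentral-t closed form, within 5 points
        n, effect, n_rep = 31, 0.5, 200
        hits = 0
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            X = effect + r.standard_normal((n, 1))
            hits += bool(channelwise_t(X)["flagged"][0])
        t_crit = stats.t.isf(0.05, n - 1)
        power = stats.nct.sf(t_crit, n - 1, effect * np.sqrt(n))
        assert abs(hits / n_rep - power) < 0.05

    def test_missing_channels_accounted_per_channel(self, rng):
        X = rng.standard_normal((10, 3))
        X[:5, 1] = np.nan
        out = channelwise_t(X)
        assert list(out["n"]) == [10, 5, 10]

    def test_df_is_n_minus_one(self, rng):
        out = channelwise_t(rng.standard_normal((31, 4)))
        # recompute p from t at df=30 and compare
        p = stats.t.sf(out["t"], 30)
        np.testing.assert_allclose(out["p"], p, atol=1e-12)


class TestDualCriterion:
    def _setup(self, cluster_size, channel_p, rng):
        grid = toy_grid((10, 10, 10))
        values = np.zeros(1000)
        values[:cluster_size] = 10.0
        tmap = VolumeMap(grid=grid, values=values, df=30)
        table, labels = threshold_and_cluster(tmap, return_labels=True)
        # one channel at the cluster, one far away
        coords = np.array([[0.0, 0.0, 0.0], [500.0, 500.0, 500.0]])
        channel_stats = pd.DataFrame({
            "channel": [1, 2],
            "n": [31, 31],
            "t": [3.0, 0.1],
            "p": [channel_p, 0.46],
            "flagged": [channel_p < 0.05, False],
        })
        return dual_criterion(table, labels, grid, channel_stats, coords)

    def test_cluster_plus_channel_is_significant(self, rng):
        findings = self._setup(cluster_size=100, channel_p=0.01, rng=rng)
        assert list(findings["label"]) == ["significant"]
        assert findings["channels"].iloc[0] == [1]

    def test_subthreshold_cluster_with_channel_is_active(self, rng):
        findings = self._setup(cluster_size=40, channel_p=0.01, rng=rng)
        assert list(findings["label"]) == ["active"]

    def test_no_clusters_no_channels_empty(self, rng):
        findings = self._setup(cluster_size=0, channel_p=0.5, rng=rng)
        assert findings.empty

    def test_unsupported_cluster_dropped(self, rng):
        findings = self._setup(cluster_size=100, channel_p=0.5, rng=rng)
        assert findings.empty


class TestOverlapFraction:
    def test_subset_gives_one(self):
        a = np.zeros((4, 4, 4), bool)
        a[1, 1, 1] = True
        b = np.ones((4, 4, 4), bool)
        assert overlap_fraction(a, b) == 1.0

    def test_disjoint_gives_zero(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert overlap_fraction(a, b) == 0.0

    def test_23_of_100(self):
        a = np.zeros(200, bool)
        b = np.zeros(200, bool)
        a[:100] = True
        b[77:100] = True
        assert overlap_fraction(a, b) == pytest.approx(0.23)

    def test_empty_a_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_fraction(np.zeros(5, bool), np.ones(5, bool))
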