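"""SMLM post-processing: filtering, blink merging, drift, g(r), DBSCAN."""

import numpy as np
import pandas as pd
import pytest

from tcrquant.localization_stats import (
    LocalizationTable,
    RegionMask,
    dbscan_clusters,
    drift_correct,
    filter_localizations,
    merge_blinks,
    pair_autocorrelation,
)
from tcrquant.synthetic_data import PointPatternTruth, simulate_localizations

from conftest import csr_table


def naive_dbscan(xy: np.ndarray, eps: float, min_neighbors: int) -> np.ndarray:
    """Classic density-based clustering by direct O(n^2) neighbor counting.

    Points are scanned in index order; border points join the first cluster
    that reaches them.
    """
    n = len(xy)
    d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
    neigh = [np.where((d2[i] <= eps**2) & (np.arange(n) != i))[0] for i in range(n)]
    core = np.array([len(nb) >= min_neighbors for nb in neigh])
    labels = np.full(n, -1)
    cluster = -1
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        cluster += 1
        labels[i] = cluster
        queue = [i]
        while queue:
            j = queue.pop(0)
            for k in neigh[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        queue.append(k)
    return labels


def pairwise_g(xy: np.ndarray, side: float, edges: np.ndarray) -> np.ndarray:
    """Direct O(n^2) pair-correlation estimator on a square window.

    Expected ordered pair counts per annulus under CSR come from the set
    covariance of the square, integrated numerically in polar coordinates.
    """
    from scipy.spatial.distance import pdist

    n = len(xy)
    counts = np.histogram(pdist(xy), bins=edges)[0] * 2.0  # ordered pairs
    g = np.empty(len(edges) - 1)
    for k in range(len(edges) - 1):
        r0, r1 = edges[k], edges[k + 1]
        rs = np.linspace(r0 + (r1 - r0) / 200, r1, 100)
        th = np.linspace(0, 2 * np.pi, 1440, endpoint=False)
        R, T = np.meshgrid(rs, th)
        gam = np.maximum(side - np.abs(R * np.cos(T)), 0) * np.maximum(side - np.abs(R * np.sin(T)), 0)
        integral = (gam * R).mean() * (r1 - r0) * 2 * np.pi
        g[k] = counts[k] / (n * (n - 1) / side**4 * integral)
    return g


class TestFilter:
    def test_threshold_is_strict(self):
        rec = pd.DataFrame({"x_nm": [0.0, 1.0, 2.0], "y_nm": [0.0] * 3, "frame": [0, 1, 2], "photons": [400, 401, 399]})
        out = filter_localizations(LocalizationTable(rec))
        assert out.records["photons"].tolist() == [401]

    def test_empty_input_empty_output(self):
        rec = pd.DataFrame({"x_nm": [], "y_nm": [], "frame": [], "photons": []})
        assert len(filter_localizations(LocalizationTable(rec))) == 0


class TestMergeBlinks:
    def _table(self, x, y, frames, photons=None):
        n = len(x)
        rec = pd.DataFrame(
            {"x_nm": x, "y_nm": y, "frame": frames, "photons": photons or [500.0] * n}
        )
        return LocalizationTable(rec, pixel_size_nm=107.0)

    def test_five_consecutive_frames_merge_to_one(self):
        out = merge_blinks(self._table([10.0] * 5, [10.0] * 5, list(range(5))))
        assert len(out) == 1
        assert out.records["photons"].iloc[0] == 2500.0
        assert out.records["n_frames"].iloc[0] == 5

    def test_two_pixels_apart_not_merged(self):
        out = merge_blinks(self._table([0.0, 220.0], [0.0, 0.0], [0, 1]))
        assert len(out) == 2

    def test_seven_frame_chain_splits_five_plus_two(self):
        # brute-force chain walk: cap at 5 frames then restart
        out = merge_blinks(self._table([10.0] * 7, [10.0] * 7, list(range(7))))
        assert sorted(out.records["n_frames"].tolist()) == [2, 5]

    def test_photon_weighted_centroid(self):
        out = merge_blinks(self._table([0.0, 30.0], [0.0, 0.0], [0, 1], photons=[100.0, 300.0]))
        assert len(out) == 1
        assert out.records["x_nm"].iloc[0] == pytest.approx(22.5)

    def test_idempotent_on_simulated_data(self, square_mask):
        truth = PointPatternTruth(
            n_clusters=20, molecules_per_cluster_mean=15.0, background_density=5.0,
            blink_mean=3.0, loc_precision_sigma=10.0, mask=square_mask, seed=5,
        )
        m1 = merge_blinks(simulate_localizations(truth))
        m2 = merge_blinks(m1)
        assert len(m1) == len(m2)
        np.testing.assert_allclose(m1.records["x_nm"], m2.records["x_nm"])

    def test_requires_pixel_size(self):
        t = self._table([0.0], [0.0], [0])
        t.pixel_size_nm = None
        with pytest.raises(ValueError, match="pixel"):
            merge_blinks(t)


class TestDriftCorrect:
    def _pattern(self, seed, square_mask):
        truth = PointPatternTruth(
            n_clusters=60, molecules_per_cluster_mean=20.0, background_density=10.0,
            blink_mean=2.0, loc_precision_sigma=10.0, mask=square_mask, frame_count=5000, seed=seed,
        )
        return simulate_localizations(truth)

    def test_zero_drift_near_identity(self, square_mask):
        locs = self._pattern(11, square_mask)
        out = drift_correct(locs, segment_frames=500, bin_nm=20.0)
        resid = np.hypot(out.records["x_nm"] - locs.records["x_nm"], out.records["y_nm"] - locs.records["y_nm"])
        assert resid.mean() <= 20.0

    def test_injected_linear_drift_removed(self, square_mask):
        locs = self._pattern(12, square_mask)
        rec = locs.records.copy()
        fr = rec["frame"].to_numpy()
        d = 50.0 * fr / fr.max()
        rec["x_nm"] += d
        rec["y_nm"] += 0.6 * d
        drifted = LocalizationTable(rec, pixel_size_nm=107.0, mask=square_mask)
        out = drift_correct(drifted, segment_frames=500, bin_nm=20.0)
        resid = np.hypot(out.records["x_nm"] - locs.records["x_nm"], out.records["y_nm"] - locs.records["y_nm"])
        assert resid.mean() <= 20.0  # within one bin

    def test_single_segment_identity_with_warning(self, square_mask):
        truth = PointPatternTruth(n_clusters=5, background_density=5.0, mask=square_mask, frame_count=100, seed=13)
        locs = simulate_localizations(truth)
        with pytest.warns(UserWarning, match="identity"):
            out = drift_correct(locs, segment_frames=500)
        pd.testing.assert_frame_equal(out.records, locs.records)

    def test_sparse_segment_interpolated_with_warning(self, square_mask):
        locs = self._pattern(14, square_mask)
        rec = locs.records[(locs.records["frame"] < 1000) | (locs.records["frame"] >= 1500)].reset_index(drop=True)
        keep_few = locs.records[(locs.records["frame"] >= 1000) & (locs.records["frame"] < 1500)].head(3)
        rec = pd.concat([rec, keep_few], ignore_index=True).sort_values("frame").reset_index(drop=True)
        t = LocalizationTable(rec, pixel_size_nm=107.0, mask=square_mask)
        with pytest.warns(UserWarning, match="interpolated"):
            drift_correct(t, segment_frames=500)


class TestPairAutocorrelation:
    def test_csr_gives_unit_g(self, square_mask):
        tab = csr_table(10_000, 5000.0, seed=1, mask=square_mask)
        curve = pair_autocorrelation(tab, r_max=500.0, bin_width=5.0)
        assert abs(curve.g.mean() - 1.0) < 0.05

    def test_csr_bias_shrinks_with_more_points(self, square_mask):
        dev = []
        for n in (1000, 10_000):
            tab = csr_table(n, 5000.0, seed=2, mask=square_mask)
            curve = pair_autocorrelation(tab, r_max=400.0, bin_width=20.0)
            dev.append(np.mean(np.abs(curve.g - 1.0)))
        assert dev[1] < dev[0]

    def test_clustered_pattern_short_range_enrichment(self, square_mask):
        truth = PointPatternTruth(
            n_clusters=30, molecules_per_cluster_mean=20.0, cluster_sigma=20.0,
            background_density=2.0, blink_mean=2.0, loc_precision_sigma=5.0, mask=square_mask, seed=3,
        )
        locs = simulate_localizations(truth)
        curve = pair_autocorrelation(locs, r_max=500.0, bin_width=5.0)
        g_short = curve.g[curve.radii_nm < 15.0].mean()
        g_long = curve.g[curve.radii_nm > 480.0].mean()
        assert g_short > g_long

    def test_fft_estimator_matches_pairwise_oracle(self, square_mask):
        tab = csr_table(2000, 5000.0, seed=4, mask=square_mask)
        edges = np.arange(0.0, 550.0, 50.0)
        curve = pair_autocorrelation(tab, r_max=500.0, bin_width=50.0)
        oracle = pairwise_g(tab.xy, 5000.0, edges)
        np.testing.assert_allclose(curve.g, oracle, rtol=0.05)

    def test_invariant_under_rigid_translation(self):
        mask = RegionMask.from_rect(2000.0, 2000.0, 20.0)
        tab = csr_table(2000, 2000.0, seed=5, mask=mask)
        c0 = pair_autocorrelation(tab, r_max=300.0, bin_width=10.0)
        rec = tab.records.copy()
        rec["x_nm"] += 12_345.0
        rec["y_nm"] -= 678.0
        moved_mask = RegionMask(mask.array, mask.pixel_nm, origin_nm=(12_345.0, -678.0))
        moved = LocalizationTable(rec, mask=moved_mask)
        c1 = pair_autocorrelation(moved, r_max=300.0, bin_width=10.0)
        np.testing.assert_allclose(c0.g, c1.g, rtol=1e-10)

    def test_invariant_under_quarter_rotation(self):
        side = 2000.0
        mask = RegionMask.from_rect(side, side, 20.0)
        tab = csr_table(2000, side, seed=6, mask=mask)
        c0 = pair_autocorrelation(tab, r_max=300.0, bin_width=10.0)
        rec = tab.records.copy()
        x, y = rec["x_nm"].copy(), rec["y_nm"].copy()
        rec["x_nm"], rec["y_nm"] = y, (side - 1e-9) - x
        c1 = pair_autocorrelation(LocalizationTable(rec, mask=mask), r_max=300.0, bin_width=10.0)
        np.testing.assert_allclose(c0.g, c1.g, rtol=1e-6)

    def test_mask_required_and_minimum_points(self):
        rec = pd.DataFrame({"x_nm": [0.0] * 60, "y_nm": [0.0] * 60, "frame": range(60), "photons": 1000.0})
        with pytest.raises(ValueError, match="mask"):
            pair_autocorrelation(LocalizationTable(rec))
        small = LocalizationTable(rec.head(10), mask=RegionMask.from_rect(100, 100))
        with pytest.raises(ValueError, match="50"):
            pair_autocorrelation(small)

    def test_rmax_truncated_to_mask_extent(self):
        mask = RegionMask.from_rect(500.0, 500.0, 20.0)
        tab = csr_table(500, 500.0, seed=7, mask=mask)
        with pytest.warns(UserWarning, match="truncat"):
            curve = pair_autocorrelation(tab, r_max=5000.0, bin_width=25.0)
        assert curve.radii_nm[-1] <= np.hypot(500.0, 500.0)


class TestDBSCAN:
    def test_all_isolated_points_are_noise(self):
        xy = np.arange(20, dtype=float) * 100.0
        rec = pd.DataFrame({"x_nm": xy, "y_nm": xy, "frame": range(20), "photons": 1000.0})
        res = dbscan_clusters(LocalizationTable(rec))
        assert res.n_clusters == 0
        assert np.all(res.labels == -1)

    def test_ten_mutually_close_points_one_cluster(self):
        rng = np.random.default_rng(8)
        xy = rng.uniform(0, 10.0, (10, 2))  # all within 25 nm of each other
        rec = pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1], "frame": range(10), "photons": 1000.0})
        res = dbscan_clusters(LocalizationTable(rec))
        assert res.n_clusters == 1
        assert res.cluster_sizes.tolist() == [10]

    def test_single_simulated_cluster_detected(self, square_mask):
        truth = PointPatternTruth(
            n_clusters=1, molecules_per_cluster_mean=20.0, cluster_sigma=10.0,
            background_density=0.0, blink_mean=1.0, loc_precision_sigma=1e-12, mask=square_mask, seed=7,
        )
        res = dbscan_clusters(simulate_localizations(truth))
        assert res.n_clusters == 1

    def test_partition_matches_naive_reference_on_random_instances(self):
        rng = np.random.default_rng(9)
        for trial in range(50):
            side = float(rng.uniform(300.0, 1500.0))
            mask = RegionMask.from_rect(side, side, 20.0)
            truth = PointPatternTruth(
                n_clusters=int(rng.integers(0, 6)),
                molecules_per_cluster_mean=float(rng.uniform(5.0, 25.0)),
                cluster_sigma=float(rng.uniform(8.0, 30.0)),
                background_density=float(rng.uniform(20.0, 120.0)),
                blink_mean=2.0,
                loc_precision_sigma=8.0,
                mask=mask,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            locs = simulate_localizations(truth)
            if len(locs) > 500:
                locs = LocalizationTable(locs.records.head(500), mask=mask)
            res = dbscan_clusters(locs)
            order = np.lexsort(
                (locs.records["frame"].to_numpy(), locs.records["y_nm"].to_numpy(), locs.records["x_nm"].to_numpy())
            )
            expected = naive_dbscan(locs.xy[order], eps=25.0, min_neighbors=7)
            np.testing.assert_array_equal(res.labels[order], expected, err_msg=f"trial {trial}")

    def test_cluster_count_monotone_in_min_neighbors(self, square_mask):
        truth = PointPatternTruth(
            n_clusters=15, molecules_per_cluster_mean=12.0, cluster_sigma=12.0,
            background_density=5.0, blink_mean=2.0, loc_precision_sigma=8.0, mask=square_mask, seed=10,
        )
        locs = simulate_localizations(truth)
        counts = [dbscan_clusters(locs, min_neighbors=k).n_clusters for k in (3, 7, 12, 20)]
        assert counts == sorted(counts, reverse=True)

    def test_summary_is_over_clusters_not_localizations(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.0, 5.0, (30, 2))
        b = rng.normal(500.0, 5.0, (10, 2))
        xy = np.vstack([a, b])
        rec = pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1], "frame": range(40), "photons": 1000.0})
        res = dbscan_clusters(LocalizationTable(rec))
        assert res.n_clusters == 2
        assert res.mean_size == pytest.approx(20.0)
        assert res.sd_size == pytest.approx(np.std([30, 10], ddof=1))
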