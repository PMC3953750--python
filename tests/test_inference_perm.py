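"""Maximum-statistic permutation inference and cluster labeling."""

from itertools import product

import numpy as np
import pytest
from scipy import ndimage

from phasefmri import fixtures as fx
from phasefmri import glm
from phasefmri import inference_perm as ip


def one_sample_design(n):
    return glm.DesignMatrix(np.ones((n, 1)), n_task=1, n_motion=0,
                            contrast=[1.0])


class TestClusterLabeling:
    def test_single_voxel(self):
        m = np.zeros((4, 4, 4))
        m[1, 2, 3] = 5.0
        lab = ip.label_clusters(m, 2.0)
        assert lab.n_clusters == 1
        assert lab.sizes.tolist() == [1]
        assert lab.masses.tolist() == [5.0]

    def test_corner_touching_voxels_join(self):
        m = np.zeros((4, 4, 4))
        m[0, 0, 0] = m[1, 1, 1] = 1.0
        assert ip.label_clusters(m, 0.5).n_clusters == 1

    def test_matches_flood_fill_oracle(self, rng):
        """Partitions equal scipy's 26-connected labeling on 100 random
        10^3 binary maps."""
        struct = np.ones((3, 3, 3))
        for seed in range(100):
            m = np.random.default_rng(seed).random((10, 10, 10))
            ours = ip.label_clusters(m, 0.75)
            oracle, n = ndimage.label(m > 0.75, structure=struct)
            assert ours.n_clusters == n
            for k in range(1, n + 1):
                sel = oracle == k
                labels = np.unique(ours.labels[sel])
                assert labels.size == 1
                assert (ours.labels == labels[0]).sum() == sel.sum()

    def test_deterministic_label_order(self):
        m = np.zeros((5, 5, 5))
        m[4, 4, 4] = 1.0   # later linear index
        m[0, 0, 0] = 1.0   # earliest linear index -> label 1
        lab = ip.label_clusters(m, 0.5)
        assert lab.labels[0, 0, 0] == 1
        assert lab.labels[4, 4, 4] == 2

    def test_extents_non_increasing_in_threshold(self, rng):
        m = ndimage.gaussian_filter(rng.standard_normal((12, 12, 12)), 1.2)
        prev = None
        for thr in (0.0, 0.2, 0.4, 0.6):
            lab = ip.label_clusters(m, thr)
            largest = lab.sizes.max() if lab.n_clusters else 0
            if prev is not None:
                assert largest <= prev
            prev = largest


class TestPvaluesAndThresholds:
    def test_observed_below_all_null(self):
        null = ip.NullDistribution(np.arange(1.0, 11.0))
        assert ip.corrected_pvalues(np.array([0.5]), null)[0] == 1.0

    def test_tie_counts_via_geq(self):
        null = ip.NullDistribution(np.arange(1.0, 101.0))
        assert ip.corrected_pvalues(np.array([100.0]), null)[0] == 0.01

    def test_exhaustive_enumeration_oracle(self):
        """p-values from the full n=5 sign-flip null match a direct
        enumeration of all 32 sign patterns."""
        rng = np.random.default_rng(3)
        y = rng.standard_normal(5) + 1.0
        null_vals = []
        for signs in product((1.0, -1.0), repeat=5):
            ys = y * np.array(signs)
            null_vals.append(ys.mean() / (ys.std(ddof=1) / np.sqrt(5)))
        null = ip.NullDistribution(np.array(null_vals))
        obs = y.mean() / (y.std(ddof=1) / np.sqrt(5))
        p = ip.corrected_pvalues(np.array([obs]), null)[0]
        expected = np.mean(np.array(null_vals) >= obs)
        assert p == expected

    def test_threshold_rank_arithmetic(self):
        null = ip.NullDistribution(np.arange(1.0, 101.0))
        assert ip.significance_threshold(null, 5.0) == 96.0
        quad = ip.NullDistribution(np.array([1.0, 2.0, 3.0, 4.0]))
        assert ip.significance_threshold(quad, 50.0) == 3.0
        with pytest.raises(ValueError):
            ip.significance_threshold(null, 0.0)

    def test_threshold_self_consistency(self, rng):
        """Applying the threshold back to its own null keeps the empirical
        exceedance at or below alpha + 1/n."""
        null = ip.NullDistribution(rng.standard_normal(500))
        for alpha in (1.0, 5.0, 10.0):
            thr = ip.significance_threshold(null, alpha)
            fwe = np.mean(null.values > thr)
            assert fwe <= alpha / 100.0 + 1.0 / null.n_permutations


class TestGroupPermutation:
    def test_smallest_achievable_p(self, rng):
        data = rng.standard_normal((4, 3, 3, 3)) + 5.0
        res = ip.permutation_test_group(data, one_sample_design(4),
                                        n_permutations=16,
                                        scheme="sign_flip", seed=0)
        assert res.null.n_permutations == 16
        assert res.p_map.min() == 1.0 / 16.0

    def test_exhaustive_null_matches_direct_oracle(self, rng):
        """Single-voxel, n=5 sign-flip enumeration equals all 32 t values."""
        y = rng.standard_normal(5) + 1.0
        res = ip.permutation_test_group(y.reshape(5, 1, 1, 1),
                                        one_sample_design(5),
                                        n_permutations=32,
                                        scheme="sign_flip", seed=0)
        oracle = sorted(
            (y * np.array(s)).mean() / ((y * np.array(s)).std(ddof=1)
                                        / np.sqrt(5))
            for s in product((1.0, -1.0), repeat=5))
        assert np.allclose(res.null.values, oracle, atol=1e-12)

    def test_observed_p_at_least_one_over_n(self, rng):
        data = rng.standard_normal((8, 4, 4, 4))
        res = ip.permutation_test_group(data, one_sample_design(8),
                                        n_permutations=100, seed=1)
        assert res.p_map.min() >= 1.0 / 100.0

    def test_seed_determinism(self, rng):
        data = rng.standard_normal((8, 4, 4, 4))
        r1 = ip.permutation_test_group(data, one_sample_design(8),
                                       n_permutations=64, seed=9)
        r2 = ip.permutation_test_group(data, one_sample_design(8),
                                       n_permutations=64, seed=9)
        assert np.array_equal(r1.null.values, r2.null.values)

    def test_cluster_inference_returns_cluster_p(self, rng):
        base = np.random.default_rng(0).standard_normal((8, 6, 6, 6))
        base[:, 2:4, 2:4, 2:4] += 4.0
        res = ip.permutation_test_group(base, one_sample_design(8),
                                        n_permutations=64,
                                        inference="cluster_extent",
                                        cdt=2.0, seed=2)
        assert res.clusters is not None and res.clusters.n_clusters >= 1
        assert res.cluster_p.min() <= 0.1

    def test_doubling_permutations_stable_p(self, rng):
        """Sign-flip exchangeability: doubling n changes p by <= 2/n on
        average across seeds."""
        data = rng.standard_normal((10, 4, 4, 4)) + 1.5
        diffs = []
        for seed in range(5):
            p1 = ip.permutation_test_group(data, one_sample_design(10),
                                           n_permutations=256,
                                           seed=seed).p_map.min()
            p2 = ip.permutation_test_group(data, one_sample_design(10),
                                           n_permutations=512,
                                           seed=seed).p_map.min()
            diffs.append(abs(p1 - p2))
        assert np.mean(diffs) <= 2.0 / 256.0


class TestFirstLevel:
    def test_surrogate_identity_reconstruction(self, rng):
        w = rng.standard_normal((5, 30))
        rho = np.tile([0.4, 0.1, 0.0, 0.0], (5, 1))
        y = glm.unwhiten_series(w, rho)
        back = ip.surrogate_first_level(glm.whiten_series(y, rho), rho,
                                        np.arange(30))
        assert np.abs(back - y).max() <= 1e-12

    def test_zero_rho_gives_plain_permutation(self, rng):
        w = rng.standard_normal((4, 20))
        perm = rng.permutation(20)
        out = ip.surrogate_first_level(w, np.zeros((4, 1)), perm)
        assert np.array_equal(out, w[:, perm])

    def test_invalid_permutation_rejected(self, rng):
        with pytest.raises(ValueError):
            ip.surrogate_first_level(rng.standard_normal((2, 10)),
                                     np.zeros((2, 1)), np.zeros(10, int))

    def test_surrogate_preserves_autocorrelation(self):
        """Surrogate lag-1 autocorrelation matches the data's within 0.05
        (T=500, rho1=0.4)."""
        rng = np.random.default_rng(4)
        T = 500
        eps = fx.generate_ar_noise(50, T, [0.4], 1.0, rng)
        rho = glm.estimate_ar_yule_walker(eps, order=4)
        w = glm.whiten_series(eps, rho)
        surr = ip.surrogate_first_level(w, rho, rng.permutation(T))

        def lag1(a):
            c = a - a.mean(axis=1, keepdims=True)
            return (np.sum(c[:, 1:] * c[:, :-1], axis=1)
                    / np.sum(c ** 2, axis=1)).mean()

        assert abs(lag1(surr) - lag1(eps)) <= 0.05

    def test_power_on_planted_activation(self):
        """A 5-sigma block activation reaches corrected p <= 0.01."""
        T = 60
        series, truth = fx.make_activation_fmri(
            (12, 12, 12), T=T, beta_effect=5.0, rho=(0.3, 0.1, 0.05, 0.02),
            sigma2=1.0, seed=5)
        task = fx.boxcar_regressor(T)
        design = glm.build_design(task[:, None], n_timepoints=T,
                                  contrast=[1.0])
        res = ip.permutation_test_first_level(series, design,
                                              n_permutations=300,
                                              smoothing_fwhm_mm=2.0, seed=3)
        assert res.p_map[truth.activation_mask].min() <= 0.01

    def test_seed_determinism(self):
        series, _ = fx.make_activation_fmri((8, 8, 8), T=40, beta_effect=0.0,
                                            rho=(0.3,), seed=2)
        design = glm.build_design(fx.boxcar_regressor(40)[:, None],
                                  n_timepoints=40, contrast=[1.0])
        runs = [ip.permutation_test_first_level(series, design,
                                                n_permutations=50,
                                                smoothing_fwhm_mm=2.0,
                                                seed=11)
                for _ in range(2)]
        assert np.array_equal(runs[0].null.values, runs[1].null.values)

    def test_type_one_error_calibration(self):
        """Voxel-level FWE on no-signal AR(4) data stays near the nominal
        5% level (the key validity property of the whiten-permute-recolor
        scheme)."""
        T = 60
        task = fx.boxcar_regressor(T)
        design = glm.build_design(task[:, None], n_timepoints=T,
                                  contrast=[1.0])
        rejections = 0
        n_rep = 100
        for rep in range(n_rep):
            series, _ = fx.make_activation_fmri(
                (10, 10, 10), T=T, beta_effect=0.0, rho=(0.4,), sigma2=1.0,
                seed=60_000 + rep)
            res = ip.permutation_test_first_level(series, design,
                                                  n_permutations=150,
                                                  smoothing_fwhm_mm=2.0,
                                                  seed=rep)
            thr = ip.significance_threshold(res.null, 5.0)
            if res.stat_map.max() > thr:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.08
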