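"""Pixel-pool statistics: pooling arithmetic, PDF normalization, KS
statistic oracles, blocked-permutation behavior, group-mean tests."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import make_null_pools
from dormaflux.correction import CalibratedImage
from dormaflux.stats import (
    PixelPool,
    anova_tukey,
    blocked_permutation_test,
    compute_pdf,
    ks_statistic,
    log2_fold_change,
    naive_permutation_test,
    pool_pixels,
)


def image(values, mouse, probe="NBDG", timepoint="primary", mask=None):
    return CalibratedImage(
        pixels=np.asarray(values, dtype=float), probe=probe,
        mouse_id=mouse, timepoint=timepoint, valid_mask=mask,
    )


class TestPooling:
    def test_two_images_pool_all_pixels_with_labels(self):
        pool = pool_pixels([image(np.ones((2, 2)), "m1"), image(2 * np.ones((2, 2)), "m2")])
        assert len(pool) == 8
        assert pool.mice == ["m1", "m2"]

    def test_flagged_pixels_excluded(self):
        mask = np.ones((4, 4), dtype=bool)
        mask.ravel()[:3] = False
        pool = pool_pixels([image(np.ones((4, 4)), "m1", mask=mask)])
        assert len(pool) == 13

    def test_pool_mean_is_weighted_mean_of_images(self):
        rng = np.random.default_rng(0)
        imgs = [image(rng.random((3, 5)), f"m{i}") for i in range(4)]
        pool = pool_pixels(imgs)
        expected = np.mean([im.pixels for im in imgs])
        assert pool.values.mean() == pytest.approx(expected)

    def test_mixed_probes_rejected(self):
        with pytest.raises(ValueError, match="probe"):
            pool_pixels([image(np.ones((2, 2)), "m1", probe="NBDG"),
                         image(np.ones((2, 2)), "m2", probe="TMRE")])


class TestPDF:
    def test_constant_pool_single_bin_and_mean(self):
        pool = PixelPool(np.full(50, 3.0), np.full(50, "m1", dtype=object))
        curve = compute_pdf(pool, n_bins=10)
        assert curve.group_mean == 3.0
        assert (curve.densities > 0).sum() == 1

    def test_uniform_density_near_one(self):
        rng = np.random.default_rng(1)
        pool = PixelPool(rng.random(200_000), np.full(200_000, "m", dtype=object))
        curve = compute_pdf(pool, n_bins=10, vmax=1.0)
        np.testing.assert_allclose(curve.densities, 1.0, atol=0.03)

    def test_normalization_sums_to_one(self):
        rng = np.random.default_rng(2)
        pool = PixelPool(rng.gamma(2.0, 3.0, 5000), np.full(5000, "m", dtype=object))
        curve = compute_pdf(pool, n_bins=37)
        widths = np.diff(curve.bin_edges)
        assert float((curve.densities * widths).sum()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_pool_and_bad_bins_error(self):
        pool = PixelPool(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            compute_pdf(pool)
        good = PixelPool(np.ones(3), np.full(3, "m", dtype=object))
        with pytest.raises(ValueError):
            compute_pdf(good, n_bins=1)


class TestKSStatistic:
    def test_identical_pools_zero(self):
        v = np.array([1.0, 2.0, 5.0])
        assert ks_statistic(v, v) == 0.0

    def test_disjoint_supports_one(self):
        assert ks_statistic([1, 2, 3], [10, 11, 12]) == 1.0

    def test_hand_enumerated_example(self):
        # ECDFs of {1,2,3} and {2,3,4} differ by at most 1/3
        assert ks_statistic([1, 2, 3], [2, 3, 4]) == pytest.approx(1 / 3)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(size=rng.integers(5, 200))
            b = rng.normal(0.3, 1.2, size=rng.integers(5, 200))
            assert ks_statistic(a, b) == pytest.approx(
                sps.ks_2samp(a, b).statistic, abs=1e-12
            )


class TestBlockedPermutation:
    def test_2v2_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        pa, pb = make_null_pools(rng, n_mice=2, n_px=40)
        res = blocked_permutation_test(pa, pb, n_perm=1000, seed=0)
        assert res.exhaustive
        assert res.n_permutations == 6  # C(4,2)
        assert res.p_empirical in {k / 6 for k in range(1, 7)}

    def test_single_mouse_group_rejected(self):
        pa = PixelPool(np.ones(10), np.full(10, "a1", dtype=object))
        pb = PixelPool(np.ones(10), np.full(10, "b1", dtype=object))
        with pytest.raises(ValueError, match="2 mice"):
            blocked_permutation_test(pa, pb)

    def test_sampled_p_add_one_floor_when_d_obs_maximal(self):
        # groups fully separated: D_obs = 1 and only re-draws of the observed
        # partition can tie it, so p sits at (1 + #ties) / (n_perm + 1) and
        # can never be 0
        rng = np.random.default_rng(1)
        pa, pb = make_null_pools(rng, n_mice=4, n_px=30, icc_sd=0.01, shift=20.0)
        res = blocked_permutation_test(pa, pb, n_perm=50, seed=2, exhaustive=False)
        assert not res.exhaustive
        assert res.D_obs == 1.0
        ties = int(np.count_nonzero(res.permutation_Ds >= res.D_obs - 1e-12))
        assert res.p_empirical == pytest.approx((1 + ties) / 51)
        assert res.p_empirical >= 1 / 51
        assert np.all(res.permutation_Ds[res.permutation_Ds < 1.0] < res.D_obs)

    def test_exhaustive_and_sampled_agree_3v3(self):
        rng = np.random.default_rng(4)
        pa, pb = make_null_pools(rng, n_mice=3, n_px=60, shift=0.5)
        exact = blocked_permutation_test(pa, pb, n_perm=1000, seed=0)
        sampled = blocked_permutation_test(
            pa, pb, n_perm=10_000, seed=1, exhaustive=False
        )
        assert exact.exhaustive and not sampled.exhaustive
        assert sampled.p_empirical == pytest.approx(exact.p_empirical, abs=0.02)

    def test_forced_exhaustive_with_insufficient_nperm_errors(self):
        rng = np.random.default_rng(5)
        pa, pb = make_null_pools(rng, n_mice=5, n_px=10)
        with pytest.raises(ValueError, match="exceed"):
            blocked_permutation_test(pa, pb, n_perm=10, exhaustive=True)

    def test_blocked_valid_naive_inflated_under_mouse_correlation(self):
        # smaller replicate of the validity study: strong mouse random effect,
        # identical group distributions
        rng = np.random.default_rng(6)
        rej_b = rej_n = 0
        n_sims = 120
        for s in range(n_sims):
            pa, pb = make_null_pools(rng, n_mice=5, n_px=80)
            rej_b += blocked_permutation_test(pa, pb, n_perm=1000, seed=s).p_empirical < 0.05
            rej_n += naive_permutation_test(pa, pb, n_perm=59, seed=s).p_empirical < 0.05
        assert rej_b / n_sims < 0.12
        assert rej_n / n_sims > 0.5


class TestGroupMeans:
    def test_equal_means_zero_fc(self):
        res = log2_fold_change([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.log2fc == 0.0

    def test_ratio_8_over_2_gives_2(self):
        res = log2_fold_change([8.0, 8.0], [2.0, 2.0])
        assert res.log2fc == pytest.approx(2.0)

    def test_simulated_effect_recovered(self):
        rng = np.random.default_rng(7)
        estimates = []
        for _ in range(200):
            a = 2.0 * np.exp(0.2 * rng.standard_normal(10))
            b = 1.0 * np.exp(0.2 * rng.standard_normal(10))
            estimates.append(log2_fold_change(a, b).log2fc)
        assert np.median(estimates) == pytest.approx(1.0, abs=0.15)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change([0.0, 0.0], [1.0, 1.0])

    def test_welch_p_matches_scipy(self):
        a = [1.0, 1.4, 0.9, 1.2]
        b = [2.0, 2.2, 1.8, 2.5]
        res = log2_fold_change(a, b)
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert res.p_value == pytest.approx(p)


class TestAnovaTukey:
    def test_identical_constants_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            F, p, pairs = anova_tukey([[3.0, 3.0], [3.0, 3.0], [3.0, 3.0]])
        assert (F, p) == (0.0, 1.0)
        assert all(v == 1.0 for v in pairs.values())

    def test_null_p_uniform(self):
        rng = np.random.default_rng(8)
        ps = [
            anova_tukey([rng.normal(size=6) for _ in range(3)])[1]
            for _ in range(400)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_two_groups_tukey_equals_anova(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=8), rng.normal(0.5, 1, size=8)
        F, p, pairs = anova_tukey([a, b], labels=["a", "b"])
        (pair_p,) = pairs.values()
        assert pair_p == pytest.approx(p, abs=1e-6)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([[1.0], [2.0, 3.0]])
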