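"""Resampling statistics: KS with bootstrap null, density permutation test,
distance covariance, Pearson channel correlations, chi-square, median ratio."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import evtirf as ev
from evtirf.stats import FrequencySummary, benjamini_hochberg, silverman_bandwidth

count_lists = st.lists(st.integers(min_value=0, max_value=20), min_size=1, max_size=20)


def brute_force_ks(x, y):
    """Max ECDF difference over every threshold in the pooled support."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    best = 0.0
    for t in np.concatenate([x, y]):
        best = max(best, abs((x <= t).mean() - (y <= t).mean()))
    return best


def dcov_double_sum(x, y):
    """n * V_n^2 via the explicit O(n^2) expansion S1 + S2 - 2*S3."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    s1 = (a * b).mean()
    s2 = a.mean() * b.mean()
    s3 = (a.mean(axis=1) * b.mean(axis=1)).mean()
    return n * (s1 + s2 - 2 * s3)


class TestFrequencyDistribution:
    def test_all_zeros(self):
        fs = ev.frequency_distribution([0, 0, 0, 0])
        assert fs.zero_fraction == 1.0
        assert fs.median == 0.0
        assert fs.frequencies.sum() == 1.0

    def test_uniform_values(self):
        fs = ev.frequency_distribution([0, 1, 2, 3, 4])
        assert np.allclose(fs.frequencies.to_numpy(), 0.2)
        assert fs.median == 2.0
        assert fs.zero_fraction == 0.2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.frequency_distribution([])


class TestKSStatistic:
    def test_identical_multisets_zero(self):
        assert ev.ks_statistic([1, 2, 2, 5], [2, 5, 1, 2]) == 0.0

    def test_disjoint_supports_one(self):
        assert ev.ks_statistic([0, 1, 2], [10, 11, 12]) == 1.0

    @given(count_lists, count_lists)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_and_symmetry(self, x, y):
        d = ev.ks_statistic(x, y)
        assert d == pytest.approx(brute_force_ks(x, y), abs=1e-12)
        assert d == pytest.approx(ev.ks_statistic(y, x), abs=1e-12)
        assert 0.0 <= d <= 1.0

    @given(count_lists, count_lists)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_under_monotone_relabeling(self, x, y):
        f = lambda v: np.exp(np.asarray(v, float)) + 3 * np.asarray(v, float)
        assert ev.ks_statistic(x, y) == pytest.approx(
            ev.ks_statistic(f(x), f(y)), abs=1e-12)

    def test_agrees_with_scipy_on_tied_data(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x, y = rng.poisson(3, 30), rng.poisson(4, 25)
            assert ev.ks_statistic(x, y) == pytest.approx(
                sps.ks_2samp(x, y).statistic, abs=1e-12)


class TestKSBootstrap:
    def test_constant_identical_samples_p_one(self):
        res = ev.ks_bootstrap_pvalue([3, 3, 3], [3, 3, 3], n_b=100, seed=0)
        assert res.statistic_value == 0.0
        assert res.p_value == 1.0

    def test_power_against_shifted_poisson(self):
        hits = 0
        for r in range(200):
            rng = np.random.default_rng(5000 + r)
            x, y = rng.poisson(3, 100), rng.poisson(8, 100)
            if ev.ks_bootstrap_pvalue(x, y, n_b=500, rng=rng).p_value < 0.01:
                hits += 1
        assert hits / 200 >= 0.99

    def test_seeded_reproducibility(self):
        x, y = [0, 1, 2, 3] * 5, [1, 2, 3, 4] * 5
        a = ev.ks_bootstrap_pvalue(x, y, n_b=300, seed=11)
        b = ev.ks_bootstrap_pvalue(x, y, n_b=300, seed=11)
        assert a.p_value == b.p_value

    def test_p_floor_is_add_one(self):
        x, y = [0] * 20, [50] * 20
        res = ev.ks_bootstrap_pvalue(x, y, n_b=99, seed=1)
        assert res.p_value >= 1 / 100


class TestDensityPermutationTest:
    def test_identical_samples_p_one(self):
        x = [1, 2, 3, 4, 5]
        res = ev.permutation_density_test(x, x, n_perm=200, seed=0)
        assert res.statistic_value == pytest.approx(0.0, abs=1e-15)
        assert res.p_value == 1.0

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(3, 100)
        y = rng.poisson(3, 100) + 30
        res = ev.permutation_density_test(x, y, n_perm=500, rng=rng)
        assert res.p_value <= 0.01

    def test_degenerate_pooled_sample(self):
        res = ev.permutation_density_test([2, 2, 2], [2, 2], n_perm=100, seed=0)
        assert res.p_value == 1.0
        assert res.extra.get("degenerate")

    def test_silverman_bandwidth_positive_scaling(self):
        rng = np.random.default_rng(2)
        pooled = rng.normal(0, 2, 400)
        h = silverman_bandwidth(pooled)
        assert 0 < h < 2


class TestDistanceCovariance:
    def test_constant_argument_gives_zero(self):
        assert ev.distance_covariance(np.ones(8), np.arange(8)) == 0.0
        assert ev.distance_covariance(np.arange(8), np.full(8, 2.5)) == 0.0

    def test_matches_double_sum_on_hand_vectors(self):
        x = np.array([1.0, 3.0, 0.0, 7.0, 2.0])
        y = np.array([2.0, 2.0, 5.0, 1.0, 9.0])
        assert ev.distance_covariance(x, y) == pytest.approx(
            dcov_double_sum(x, y), rel=1e-12)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=10),
           st.floats(-100, 100))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariant_under_additive_shift(self, xs, c):
        x = np.asarray(xs)
        y = np.linspace(0, 1, len(x))
        assert ev.distance_covariance(x + c, y) == pytest.approx(
            ev.distance_covariance(x, y), rel=1e-9, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.distance_covariance([1, 2], [1, 2, 3])

    def test_perfect_dependence_positive_control(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 50)
        assert ev.distance_covariance(x, x) > 0
        res = ev.dcov_bootstrap_test(x, x, n_b=500, seed=4, method="permutation")
        assert res.p_value <= 0.01

    def test_bootstrap_seeded_determinism(self):
        rng = np.random.default_rng(5)
        x, y = rng.poisson(3, 30), rng.poisson(3, 30)
        a = ev.dcov_bootstrap_test(x, y, n_b=200, seed=6)
        b = ev.dcov_bootstrap_test(x, y, n_b=200, seed=6)
        assert a.p_value == b.p_value and a.statistic_value == b.statistic_value


class TestPearsonMatrix:
    def table(self, data):
        return pd.DataFrame(data, columns=[f"intensity_ch{i}" for i in range(4)])

    def test_identical_channels_r_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(100, 20, 50)
        r, p = ev.pearson_matrix(self.table(np.column_stack([v, v, v, v])))
        off = r.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_independent_channels_near_zero(self):
        from evtirf.simulate import sample_amplitudes
        amps = sample_amplitudes(500, np.random.default_rng(1))
        r, _ = ev.pearson_matrix(self.table(amps))
        off = r.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) <= 0.15)

    def test_programmed_correlation_recovered(self):
        rng = np.random.default_rng(2)
        cov = np.full((4, 4), 0.8)
        np.fill_diagonal(cov, 1.0)
        data = rng.multivariate_normal(np.zeros(4), cov, size=500)
        r, p = ev.pearson_matrix(self.table(data))
        off = r.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off - 0.8) <= 0.1)
        assert np.all(p.to_numpy()[~np.eye(4, dtype=bool)] < 1e-6)

    def test_zero_variance_channel_reported_missing(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 1, (20, 4))
        data[:, 2] = 7.0
        r, _ = ev.pearson_matrix(self.table(data))
        assert np.isnan(r.iloc[0, 2])
        assert r.iloc[2, 2] == 1.0


class TestChiSquare:
    def test_identical_counts_chi2_zero(self):
        res = ev.chisq_population_test([5, 10, 20], [5, 10, 20])
        assert res.statistic_value == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_2x2(self):
        res = ev.chisq_population_test([10, 20], [20, 10])
        assert res.statistic_value == pytest.approx(20 / 3, rel=1e-12)
        assert res.extra["dof"] == 1

    def test_symmetric_in_samples(self):
        rng = np.random.default_rng(4)
        a = rng.integers(5, 50, 15)
        b = rng.integers(5, 50, 15)
        r1 = ev.chisq_population_test(a, b)
        r2 = ev.chisq_population_test(b, a)
        assert r1.statistic_value == pytest.approx(r2.statistic_value, rel=1e-12)

    def test_rare_classes_pooled(self):
        a = [100, 80, 30, 1, 0, 1]
        b = [90, 85, 25, 0, 1, 0]
        res = ev.chisq_population_test(a, b)
        # the pooled bucket grows (absorbing the third class) until its
        # expected count clears the threshold: 2 kept classes + 1 pooled
        assert res.extra["classes_kept"] == 3
        assert res.extra["dof"] == 2

    def test_null_calibration(self):
        rng = np.random.default_rng(5)
        comp = np.asarray(ev.default_composition())
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            a = rng.multinomial(500, comp)
            b = rng.multinomial(500, comp)
            if ev.chisq_population_test(a, b).p_value <= 0.05:
                rejections += 1
        lo, hi = sps.binom.ppf([0.005, 0.995], n_rep, 0.05)
        assert lo <= rejections <= hi

    def test_fewer_than_two_classes_rejected(self):
        with pytest.raises(ValueError):
            ev.chisq_population_test([3], [4])


class TestMedianFold:
    def test_threefold(self):
        mf = ev.median_fold([3, 3, 3], [1, 1, 1])
        assert mf.value == 3.0 and mf.finite

    def test_identical_samples(self):
        assert ev.median_fold([2, 4, 6], [2, 4, 6]).value == 1.0

    def test_zero_denominator_flagged_infinite(self):
        mf = ev.median_fold([3, 3], [0, 0])
        assert not mf.finite and np.isinf(mf.value)


class TestPopulationKS:
    def test_detects_single_suppressed_class(self):
        """A threefold suppression of one class (inhibitor-treatment style)
        is flagged for that class only; unchanged classes stay nonsignificant."""
        rng = np.random.default_rng(7)
        labels = ["A", "B", "C"]
        a = pd.DataFrame({"A": rng.poisson(6, 80), "B": rng.poisson(4, 80),
                          "C": rng.poisson(5, 80)})
        b = pd.DataFrame({"A": rng.poisson(2, 80), "B": rng.poisson(4, 80),
                          "C": rng.poisson(5, 80)})
        res = ev.population_ks_tests(a, b, labels, n_b=500, seed=1, bh_adjust=True)
        assert res.set_index("label").loc["A", "p_value"] < 0.01
        assert (res.set_index("label").loc[["B", "C"], "p_value"] > 0.05).all()
        assert "p_bh" in res.columns


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 15)
        ours = benjamini_hochberg(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref)
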