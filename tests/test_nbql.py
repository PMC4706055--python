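import numpy as np
import pytest
from scipy import optimize, stats

from windowdb.abundance_filter import ave_log_cpm
from windowdb.counting import CountingParams, WindowCountMatrix
from windowdb.genomic_io import GenomicInterval
from windowdb.nbql import (
    DispersionFit,
    contrast_vector,
    design_from_groups,
    estimate_dispersion_trend,
    fit_nb_glm,
    mds_distances,
    nb_deviance,
    ql_f_test,
    ql_fit,
    _fit_f_dist,
)
from windowdb.normalization import NormalizationResult, effective_offsets
from windowdb.simulate import simulate_counts

LN2 = np.log(2.0)
X2, LABELS = design_from_groups(["A", "A", "B", "B"])
CONTRAST = contrast_vector(LABELS, "B-A")


def _wrap(counts, totals=None):
    counts = np.atleast_2d(counts)
    totals = np.asarray(totals if totals is not None else [10**6] * counts.shape[1])
    windows = [GenomicInterval("sim", i * 1000, i * 1000 + 150) for i in range(len(counts))]
    return WindowCountMatrix(windows, counts, totals,
                             CountingParams(width=150, spacing=50, ext=100, min_total=0))


def oracle_nb_loglik(y, mu, phi):
    """Independent NB log-likelihood via scipy's nbinom parametrization."""
    if phi == 0:
        return float(np.sum(stats.poisson.logpmf(y, mu)))
    r = 1.0 / phi
    p = r / (r + np.asarray(mu))
    return float(np.sum(stats.nbinom.logpmf(y, r, p)))


class TestFitNbGlm:
    def test_poisson_intercept_fit_is_arithmetic_mean(self):
        y = np.array([3, 7, 11, 19])
        X = np.ones((4, 1))
        _, mu, _ = fit_nb_glm(y, X, np.zeros(4), 0.0)
        np.testing.assert_allclose(mu, y.mean(), rtol=1e-8)

    def test_saturated_fit_zero_deviance(self):
        y = np.array([4.0, 9.0])
        X = np.eye(2)
        _, mu, dev = fit_nb_glm(y, X, np.zeros(2), 0.2)
        np.testing.assert_allclose(mu, y, rtol=1e-6)
        assert dev == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.5])
    def test_matches_direct_likelihood_maximization(self, phi):
        rng = np.random.default_rng(29)
        for _ in range(8):
            y = rng.integers(0, 60, size=4).astype(float)
            off = rng.normal(0, 0.3, size=4)
            beta, mu, _ = fit_nb_glm(y, X2, off, phi)
            ll_mine = oracle_nb_loglik(y, mu, phi)

            def negll(b):
                return -oracle_nb_loglik(y, np.exp(off + X2 @ b), phi)

            res = optimize.minimize(negll, beta + 0.05, method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12})
            assert ll_mine >= -res.fun - 1e-4

    def test_offset_contract(self):
        # adding a constant to one observation's offset shifts nothing but
        # that observation's contribution; adding a constant to ALL offsets
        # of a library with its own coefficient shifts that coefficient
        y = np.array([10, 12, 40, 44])
        b0, _, _ = fit_nb_glm(y, X2, np.zeros(4), 0.1)
        shift = 0.7
        off = np.array([0.0, 0.0, shift, shift])  # group B libraries
        b1, _, _ = fit_nb_glm(y, X2, off, 0.1)
        assert b1[0] == pytest.approx(b0[0], abs=1e-6)
        assert b1[1] == pytest.approx(b0[1] - shift, abs=1e-6)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError):
            fit_nb_glm(np.ones(4), X, np.zeros(4), 0.1)


class TestDispersionTrend:
    def test_recovers_constant_dispersion(self):
        m, _ = simulate_counts(4000, X2, 0.0, phi=0.05, df_prior_true=np.inf, seed=30)
        off = effective_offsets(m, NormalizationResult(mode="factors", factors=np.ones(4)))
        disp = estimate_dispersion_trend(m, X2, off)
        A = ave_log_cpm(m)
        mid = (A > np.quantile(A, 0.2)) & (A < np.quantile(A, 0.8))
        assert disp.trended[mid].min() > 0.04
        assert disp.trended[mid].max() < 0.06

    def test_poisson_data_near_zero_dispersion(self):
        m, _ = simulate_counts(3000, X2, 0.0, phi=0.0, df_prior_true=np.inf, seed=31)
        off = effective_offsets(m, NormalizationResult(mode="factors", factors=np.ones(4)))
        disp = estimate_dispersion_trend(m, X2, off)
        assert np.all(disp.trended < 0.005)

    def test_invariant_to_window_permutation(self):
        m, _ = simulate_counts(1000, X2, 0.0, phi=0.1, df_prior_true=np.inf, seed=32)
        off = effective_offsets(m, NormalizationResult(mode="factors", factors=np.ones(4)))
        d1 = estimate_dispersion_trend(m, X2, off)
        rng = np.random.default_rng(33)
        perm = rng.permutation(m.n_windows)
        m2 = WindowCountMatrix([m.windows[i] for i in perm], m.counts[perm],
                               m.totals, m.params)
        d2 = estimate_dispersion_trend(m2, X2, off[perm])
        np.testing.assert_allclose(d2.trended, d1.trended[perm], rtol=1e-10)
        assert d2.common == pytest.approx(d1.common, rel=1e-10)

    def test_no_replication_errors(self):
        m, _ = simulate_counts(100, np.eye(2), 0.0, seed=34, depths=[1e6, 1e6])
        with pytest.raises(ValueError, match="replication"):
            estimate_dispersion_trend(m, np.eye(2), np.zeros((100, 2)))


class TestQLFit:
    @staticmethod
    def _fit(seed=35, d0=20.0, robust=False, n=5000):
        m, _ = simulate_counts(n, X2, 0.0, phi=0.05, df_prior_true=d0, seed=seed)
        off = effective_offsets(m, NormalizationResult(mode="factors", factors=np.ones(4)))
        disp = estimate_dispersion_trend(m, X2, off)
        return ql_fit(m, X2, off, disp, robust=robust)

    def test_shrinkage_ordering(self):
        fit = self._fit()
        lo = np.minimum(fit.s2_raw, fit.s2_trend)
        hi = np.maximum(fit.s2_raw, fit.s2_trend)
        assert np.all(fit.s2_post >= lo - 1e-10)
        assert np.all(fit.s2_post <= hi + 1e-10)

    def test_identical_raw_dispersions_give_infinite_prior(self):
        counts = np.tile(np.array([[10, 10, 10, 10]]), (50, 1))
        m = _wrap(counts)
        off = np.full((50, 4), np.log(1e6))
        disp = DispersionFit(trended=np.full(50, 0.05), common=0.05)
        fit = ql_fit(m, X2, off, disp)
        assert np.isinf(np.atleast_1d(fit.df_prior)).all()
        np.testing.assert_allclose(fit.s2_post, fit.s2_trend)

    def test_prior_df_recovered_from_scaled_f_draws(self):
        # direct test of the moment-matching estimator on its own model
        rng = np.random.default_rng(36)
        df_res, d0_true = 2.0, 20.0
        s2 = stats.f.rvs(df_res, d0_true, size=20_000, random_state=rng)
        cov = rng.uniform(0, 10, size=20_000)
        s2_trend, d0_hat, _ = _fit_f_dist(s2, df_res, cov, robust=False)
        assert 10.0 <= d0_hat <= 40.0
        assert np.median(s2_trend) == pytest.approx(1.0, rel=0.1)

    def test_robust_prior_df_recovery(self):
        # the generative prior df maps only approximately onto the estimate
        # when the deviances come from full GLM fits rather than F draws
        fit = self._fit(d0=20.0, robust=True, n=8000)
        assert 8.0 <= np.median(np.atleast_1d(fit.df_prior)) <= 60.0

    def test_robust_outliers_get_reduced_prior_df(self):
        rng = np.random.default_rng(37)
        s2 = stats.f.rvs(2.0, 15.0, size=5000, random_state=rng)
        s2[:20] *= 100.0  # gross outliers
        cov = rng.uniform(0, 10, size=5000)
        _, d0_global, d0_win = _fit_f_dist(s2, 2.0, cov, robust=True)
        # spiked windows lose prior df (none gain); a spike starting deep in
        # the left tail may legitimately stay unflagged
        assert np.sum(d0_win[:20] < d0_global) >= 15
        assert np.all(d0_win[:20] <= d0_global)


class TestQLFTest:
    def test_identical_group_means_zero_logfc(self):
        counts = np.array([[20, 20, 20, 20], [7, 9, 9, 7]])
        m = _wrap(counts)
        off = np.full((2, 4), np.log(1e6))
        disp = DispersionFit(trended=np.full(2, 0.05), common=0.05)
        fit = ql_fit(m, X2, off, disp)
        res = ql_f_test(fit, CONTRAST)
        np.testing.assert_allclose(res.logFC, 0.0, atol=1e-6)

    def test_single_window_matches_hand_oracle(self):
        # one-hot design with equal offsets: the NB MLE of each group mean is
        # the group average, so every quantity is computable by hand
        y = np.array([[5.0, 6.0, 50.0, 60.0]])
        phi = 0.1
        m = _wrap(y.astype(int))
        off = np.zeros((1, 4))
        disp = DispersionFit(trended=np.array([phi]), common=phi)
        fit = ql_fit(m, X2, off, disp)
        res = ql_f_test(fit, CONTRAST)

        mu_full = np.array([5.5, 5.5, 55.0, 55.0])
        mu_null = np.full(4, y.mean())
        dev_full = nb_deviance(y[0], mu_full, phi)
        dev_null = nb_deviance(y[0], mu_null, phi)
        s2_post = fit.s2_post[0]
        f_expected = (dev_null - dev_full) / s2_post
        assert res.F[0] == pytest.approx(f_expected, abs=1e-6)
        d_total = np.atleast_1d(fit.df_prior)[0] + fit.df_residual
        if np.isinf(d_total):
            p_expected = stats.chi2.sf(f_expected, 1)
        else:
            p_expected = stats.f.sf(f_expected, 1, d_total)
        assert res.p_value[0] == pytest.approx(p_expected, abs=1e-6)
        assert res.logFC[0] == pytest.approx(np.log2(55.0 / 5.5), abs=1e-6)

    def test_null_pvalues_roughly_uniform(self):
        m, _ = simulate_counts(20_000, X2, 0.0, phi=0.05, df_prior_true=np.inf, seed=38)
        off = effective_offsets(m, NormalizationResult(mode="factors", factors=np.ones(4)))
        disp = estimate_dispersion_trend(m, X2, off)
        fit = ql_fit(m, X2, off, disp, robust=False)
        res = ql_f_test(fit, CONTRAST)
        assert stats.kstest(res.p_value, "uniform").statistic < 0.02

    def test_offset_shift_moves_coefficient_exactly(self):
        m, _ = simulate_counts(200, X2, 0.0, phi=0.05, df_prior_true=np.inf, seed=39)
        base = effective_offsets(m, NormalizationResult(mode="factors", factors=np.ones(4)))
        disp = DispersionFit(trended=np.full(200, 0.05), common=0.05)
        fit0 = ql_fit(m, X2, base, disp)
        shifted = base.copy()
        shifted[:, 2:] += 0.4  # both group-B libraries
        fit1 = ql_fit(m, X2, shifted, disp)
        np.testing.assert_allclose(fit1.coef[:, 1], fit0.coef[:, 1] - 0.4, atol=1e-5)
        np.testing.assert_allclose(fit1.coef[:, 0], fit0.coef[:, 0], atol=1e-5)

    def test_contrast_validation(self):
        fit = TestQLFit._fit(n=100)
        with pytest.raises(ValueError):
            ql_f_test(fit, np.zeros(2))
        with pytest.raises(ValueError):
            ql_f_test(fit, np.ones(3))


class TestMdsDistances:
    def test_identical_libraries_zero(self):
        Y = np.tile(np.arange(100, dtype=float)[:, None], (1, 3))
        np.testing.assert_allclose(mds_distances(Y), 0.0)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(40)
        Y = rng.normal(size=(500, 4))
        D = mds_distances(Y, top=100)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)

    def test_group_structure_separates(self):
        rng = np.random.default_rng(41)
        base = rng.normal(size=1000)
        shift = np.zeros(1000)
        shift[:200] = 2.0
        Y = np.column_stack([base, base + rng.normal(0, 0.05, 1000),
                             base + shift, base + shift + rng.normal(0, 0.05, 1000)])
        D = mds_distances(Y, top=300)
        assert D[0, 2] > 3 * D[0, 1]
        assert D[1, 3] > 3 * D[2, 3]
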