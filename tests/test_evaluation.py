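"""WAIC/LOO arithmetic, posterior summaries and convergence diagnostics."""

import numpy as np
import pytest
from scipy.special import logsumexp

import rangesqueeze as rs
from rangesqueeze import evaluation as ev
from rangesqueeze.models import LocalModelData, MCMCConfig, fit_local
from rangesqueeze.synthetic import TrueParameters, simulate_global_dataset


def loglik_fixture(rng, S=200, n=15):
    return rng.normal(-1.2, 0.3, (S, n))


class TestWaic:
    def test_identical_draws_zero_effective_parameters(self):
        ll = np.tile(np.array([-1.0, -2.0, -0.5]), (150, 1))
        waic, se, p_waic = ev.compute_waic(ll)
        assert p_waic == pytest.approx(0.0, abs=1e-12)
        assert waic == pytest.approx(-2 * ll[0].sum())

    def test_duplicated_dataset_doubles_waic(self, rng):
        ll = loglik_fixture(rng)
        w1, _, p1 = ev.compute_waic(ll)
        w2, _, p2 = ev.compute_waic(np.concatenate([ll, ll], axis=1))
        assert w2 == pytest.approx(2 * w1)
        assert p2 == pytest.approx(2 * p1)

    def test_matches_manual_small_table(self):
        """Hand-computed WAIC on a tiny draws x observations table."""
        ll = np.array([[-1.0, -2.0], [-1.5, -2.5]])
        ll = np.tile(ll, (50, 1))  # meet the draw-count precondition
        lppd = sum(
            logsumexp(ll[:, i]) - np.log(ll.shape[0]) for i in range(2)
        )
        p = sum(np.var(ll[:, i], ddof=1) for i in range(2))
        expected = -2 * (lppd - p)
        waic, _, p_waic = ev.compute_waic(ll)
        assert waic == pytest.approx(expected)
        assert p_waic == pytest.approx(p)

    def test_nonfinite_loglik_identifies_observation(self, rng):
        ll = loglik_fixture(rng)
        ll[3, 7] = np.inf
        with pytest.raises(ValueError, match="7"):
            ev.compute_waic(ll)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            ev.compute_waic(np.zeros((10, 4)))


class TestLoo:
    def test_identical_draws_equals_lppd(self):
        row = np.array([-1.0, -2.0, -0.5, -1.4])
        ll = np.tile(row, (200, 1))
        elpd, se, k = ev.compute_loo(ll)
        assert elpd == pytest.approx(row.sum())

    def test_order_invariance(self, rng):
        ll = loglik_fixture(rng)
        perm = rng.permutation(ll.shape[1])
        a = ev.compute_loo(ll)[0]
        b = ev.compute_loo(ll[:, perm])[0]
        assert a == pytest.approx(b)

    def test_chain_concatenation_order_invariant(self, rng):
        ll = loglik_fixture(rng, S=300)
        half = 150
        swapped = np.concatenate([ll[half:], ll[:half]])
        assert ev.compute_loo(ll)[0] == pytest.approx(ev.compute_loo(swapped)[0])


class TestProbNegative:
    @pytest.mark.parametrize(
        "draws,expected",
        [(-np.ones(100), 1.0), (np.ones(100), 0.0)],
    )
    def test_saturated_cases(self, draws, expected):
        assert ev.posterior_prob_negative(draws) == expected

    def test_symmetric_draws_near_half(self, rng):
        d = rng.normal(0, 1, 200_000)
        assert ev.posterior_prob_negative(d) == pytest.approx(0.5, abs=0.01)


class TestBayesianR2:
    def _fit(self, seed, noise, J=15, n=60):
        rng = np.random.default_rng(seed)
        v = rng.uniform(5, 15, J)
        tp = TrueParameters(alpha_V=7.5, beta_V=-0.15, sigma2_site=noise, sigma2_RS=0.25)
        y, s, _ = simulate_global_dataset(v, tp, n, seed=seed + 1)
        data = rs.GlobalModelData.from_covariates(y, s, v, "v")
        mc = MCMCConfig(n_chains=2, n_iter=3000, burn_in=1000, target_ess=0, seed=seed)
        return rs.fit_global(data, mc, store_loglik=False), data

    def test_noiseless_site_means_r2_near_one(self):
        fit, data = self._fit(40, noise=1e-6, n=400)
        r2, draws = ev.bayesian_r2(fit, data.X)
        assert r2 > 0.95

    def test_permuted_covariate_r2_near_zero(self):
        rng = np.random.default_rng(41)
        fit, data = self._fit(41, noise=0.05)
        X = data.X.copy()
        X[:, 1] = rng.permutation(X[:, 1])
        # refit against the permuted covariate: no structure left
        data2 = rs.GlobalModelData(data.y, data.site_index, X, data.coef_names)
        mc = MCMCConfig(n_chains=2, n_iter=3000, burn_in=1000, target_ess=0, seed=42)
        fit2 = rs.fit_global(data2, mc, store_loglik=False)
        r2, _ = ev.bayesian_r2(fit2, X)
        assert r2 < 0.35

    def test_r2_always_in_unit_interval(self):
        fit, data = self._fit(43, noise=0.2)
        _, draws = ev.bayesian_r2(fit, data.X)
        assert np.all((draws >= 0) & (draws <= 1))


class TestRhat:
    def test_identical_constant_chains_exactly_one(self):
        chains = np.full((3, 500), 2.5)
        assert ev.rhat(chains) == 1.0

    def test_copies_of_one_well_mixed_chain_near_one(self, rng):
        c = rng.normal(0, 1, 4000)
        assert ev.rhat(np.stack([c, c, c])) == pytest.approx(1.0, abs=0.05)

    def test_separated_chains_flagged(self, rng):
        a = rng.normal(0, 1, 1000)
        b = rng.normal(5, 1, 1000)
        r = ev.rhat(np.stack([a, b]))
        assert r > 1.5
        # cross-check against the direct between/within formula on split halves
        splits = np.stack([a[:500], b[:500], a[500:], b[500:]])
        W = np.mean(np.var(splits, axis=1, ddof=1))
        B = 500 * np.var(splits.mean(axis=1), ddof=1)
        expected = np.sqrt((499 / 500 * W + B / 500) / W)
        assert r == pytest.approx(expected)

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            ev.rhat(rng.normal(size=(1, 100)))


class TestEffectiveSampleSize:
    def test_white_noise_ess_near_total(self, rng):
        a = rng.normal(size=(3, 4000))
        ess = ev.effective_sample_size(a)
        assert abs(ess - 12000) < 1200

    def test_ar1_matches_closed_form(self, rng):
        rho, n, m = 0.9, 40_000, 2
        chains = np.empty((m, n))
        for c in range(m):
            e = rng.normal(size=n)
            x = np.empty(n)
            x[0] = e[0]
            for t in range(1, n):
                x[t] = rho * x[t - 1] + e[t]
            chains[c] = x
        ess = ev.effective_sample_size(chains)
        expected = m * n * (1 - rho) / (1 + rho)
        assert abs(ess - expected) / expected < 0.2

    def test_duplicated_chain_doubles_pooled_ess(self, rng):
        c = rng.normal(size=2000)
        one = ev.effective_sample_size(np.stack([c]))
        two = ev.effective_sample_size(np.stack([c, c]))
        # a second independent-looking copy doubles the nominal pool
        assert two == pytest.approx(2 * one, rel=0.15)

    def test_constant_chain_reports_total(self):
        assert ev.effective_sample_size(np.full((2, 300), 1.0)) == 600.0


class TestPosteriorPredictiveCheck:
    def _local_fit(self, seed=50):
        rng = np.random.default_rng(seed)
        J, n = 5, 60
        s = np.repeat(np.arange(J), n)
        v = rng.uniform(0, 5, J * n)
        y = rng.normal(6.5 - 0.2 * v, 0.6)
        data = LocalModelData(y, s, v)
        mc = MCMCConfig(n_chains=2, n_iter=3000, burn_in=1000, target_ess=0, seed=seed)
        return fit_local(data, mc, store_loglik=False), y, s, v

    def test_well_specified_data_rarely_flagged(self):
        fit, y, s, v = self._local_fit()
        rep = ev.posterior_predictive_check(fit, y, s, v, seed=1)
        assert rep["flagged"].mean() < 0.15

    def test_gross_misfit_flagged(self):
        fit, y, s, v = self._local_fit()
        rep = ev.posterior_predictive_check(fit, y * 10, s, v, seed=1)
        means = rep[rep["statistic"] == "mean"]
        assert means["flagged"].all()

    def test_deterministic_given_seed(self):
        fit, y, s, v = self._local_fit()
        a = ev.posterior_predictive_check(fit, y, s, v, seed=3)
        b = ev.posterior_predictive_check(fit, y, s, v, seed=3)
        assert a.equals(b)


class TestClassifyLocalSlopes:
    def _fit_with_betas(self, betas, sigma=0.3, n=80, seed=60):
        rng = np.random.default_rng(seed)
        J = len(betas)
        s = np.repeat(np.arange(J), n)
        v = rng.uniform(0, 6, J * n)
        alphas = rng.normal(6.5, 0.3, J)
        y = rng.normal(alphas[s] + np.asarray(betas)[s] * v, sigma)
        mc = MCMCConfig(n_chains=2, n_iter=3000, burn_in=1000, target_ess=0, seed=seed)
        return fit_local(LocalModelData(y, s, v), mc, store_loglik=False)

    def test_strong_positive_site_low_uncertainty(self):
        fit = self._fit_with_betas([0.8, -0.8, 0.6])
        df, agg = ev.classify_local_slopes(fit)
        row = df[df["site"] == 0].iloc[0]
        assert row["sign"] == "positive" and row["low_uncertainty"]

    def test_wide_ci_classified_by_mean_not_low_uncertainty(self):
        fit = self._fit_with_betas([0.01, -0.5, 0.5], sigma=2.0, n=20)
        df, _ = ev.classify_local_slopes(fit)
        row = df[df["site"] == 0].iloc[0]
        assert row["sign"] in ("positive", "negative")
        assert not row["low_uncertainty"]

    def test_aggregate_percentages_match_planted_signs(self):
        betas = [0.5] * 8 + [-0.5] * 12
        fit = self._fit_with_betas(betas, seed=61)
        df, agg = ev.classify_local_slopes(fit)
        assert agg["pct_positive"] == pytest.approx(40.0)
        assert agg["pct_negative"] == pytest.approx(60.0)
        assert agg["pct_positive_low_uncertainty"] == pytest.approx(40.0)
        assert agg["pct_negative_low_uncertainty"] == pytest.approx(60.0)

    def test_summary_invariant_to_chain_order(self):
        fit = self._fit_with_betas([0.4, -0.4])
        for name in fit.params:
            fit.params[name] = fit.params[name][::-1].copy()
        df, agg = ev.classify_local_slopes(fit)
        assert agg["pct_positive"] == pytest.approx(50.0)
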