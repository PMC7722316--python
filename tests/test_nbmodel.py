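import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from starrcall.covariates import assemble_matrix
from starrcall.nbmodel import (
    NBFit,
    NegativeBinomialRegressor,
    bh_adjust,
    fit_candidate_distributions,
    fit_nb2,
    fit_rate_mode,
    nb_logpmf,
    nb_pvalue,
    pvalue_calibration,
)


def nb_sample(rng, mu, theta, size=None):
    return rng.poisson(rng.gamma(theta, np.asarray(mu) / theta, size=size))


class TestLogPmf:
    def test_zero_count_closed_form(self):
        mu, theta = 3.0, 2.0
        assert nb_logpmf(0, mu, theta) == pytest.approx(
            theta * np.log(theta / (theta + mu)), abs=1e-14)

    def test_normalization(self):
        y = np.arange(3000)
        total = np.exp(nb_logpmf(y, 41.6, 8.9)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_poisson_limit(self):
        y = np.arange(40)
        diff = np.abs(np.exp(nb_logpmf(y, 5.0, 1e6)) - stats.poisson.pmf(y, 5.0))
        assert diff.max() < 1e-4

    @pytest.mark.parametrize("y,mu,theta", [(-1, 1, 1), (0.5, 1, 1),
                                            (1, 0, 1), (1, 1, -2)])
    def test_domain_errors(self, y, mu, theta):
        with pytest.raises(ValueError):
            nb_logpmf(y, mu, theta)


class TestPValue:
    def test_zero_count_is_one(self):
        assert nb_pvalue(0, 10.0, 3.0) == 1.0

    def test_matches_direct_summation_on_grid(self):
        """The survival value must equal the tail sum of the pmf: the
        incomplete-beta route is checked against explicit summation."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(200):
            mu = rng.uniform(0.1, 100)
            theta = rng.uniform(0.2, 50)
            y = int(rng.integers(0, 200))
            direct = 1.0 - sum(np.exp(nb_logpmf(k, mu, theta)) for k in range(y))
            worst = max(worst, abs(float(nb_pvalue(y, mu, theta)) - direct))
        assert worst < 1e-10

    def test_strictly_decreasing_in_count(self):
        y = np.arange(0, 200)
        p = nb_pvalue(y, 20.0, 8.9)
        assert (np.diff(p) < 0).all()

    def test_vectorized_and_clipped(self):
        p = nb_pvalue(np.array([0, 5, 500]), np.array([10.0, 10.0, 10.0]), 8.9)
        assert p[0] == 1.0 and 0 <= p[2] <= p[1] <= 1


class TestFit:
    def test_intercept_only_recovers_mean_and_grid_theta(self):
        rng = np.random.default_rng(0)
        y = nb_sample(rng, 41.6, 8.9, 20_000)
        est = NegativeBinomialRegressor().fit(np.empty((len(y), 0)), y)
        assert np.exp(est.intercept_) == pytest.approx(y.mean(), abs=1e-6)
        # independent oracle: profile likelihood over a dense theta grid
        grid = np.exp(np.linspace(np.log(0.5), np.log(100), 4000))
        ll = [np.sum(nb_logpmf(y, y.mean(), th)) for th in grid]
        theta_grid = grid[int(np.argmax(ll))]
        assert est.theta_ == pytest.approx(theta_grid, rel=2e-3)

    def test_parameter_recovery_known_coefficients(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20_000)
        y = nb_sample(rng, np.exp(1.0 + 0.5 * x), 8.9)
        est = NegativeBinomialRegressor().fit(x[:, None], y)
        assert est.intercept_ == pytest.approx(1.0, abs=0.05)
        assert est.coef_[0] == pytest.approx(0.5, abs=0.05)
        assert est.theta_ == pytest.approx(8.9, rel=0.15)
        assert est.converged_

    def test_loglik_nondecreasing_across_iterations(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=5000)
        y = nb_sample(rng, np.exp(2.0 + 0.8 * x), 3.0)
        est = NegativeBinomialRegressor().fit(x[:, None], y)
        assert (np.diff(est.loglik_path_) >= -1e-7).all()

    def test_agrees_with_independent_glm_implementation(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = rng.normal(size=10_000)
        y = nb_sample(rng, np.exp(1.5 - 0.4 * x), 5.0)
        est = NegativeBinomialRegressor().fit(x[:, None], y)
        ref = sm.NegativeBinomial(y, sm.add_constant(x)).fit(disp=0)
        assert est.intercept_ == pytest.approx(ref.params[0], abs=1e-4)
        assert est.coef_[0] == pytest.approx(ref.params[1], abs=1e-4)
        assert est.theta_ == pytest.approx(1 / ref.params[-1], rel=1e-4)

    def test_poisson_data_drives_dispersion_to_cap(self):
        rng = np.random.default_rng(4)
        y = rng.poisson(20.0, 20_000)
        est = NegativeBinomialRegressor().fit(np.empty((len(y), 0)), y)
        assert est.theta_ > 1e3

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            NegativeBinomialRegressor().fit(X, rng.poisson(5, 100),
                                            feature_names=["a", "a_times_2"])

    def test_aic_bic_bookkeeping(self):
        rng = np.random.default_rng(6)
        y = nb_sample(rng, 20.0, 5.0, 2000)
        est = NegativeBinomialRegressor().fit(np.empty((len(y), 0)), y)
        k = 2  # intercept + dispersion
        assert est.aic_ == pytest.approx(2 * k - 2 * est.llf_)
        assert est.bic_ == pytest.approx(k * np.log(2000) - 2 * est.llf_)

    def test_each_added_informative_covariate_lowers_aic(self):
        """Stepwise covariate assessment: with all effects programmed,
        richer nested models fit better by AIC."""
        rng = np.random.default_rng(7)
        n = 8000
        X = rng.normal(size=(n, 3))
        y = nb_sample(rng, np.exp(2.0 + 0.4 * X[:, 0] + 0.3 * X[:, 1]
                                  - 0.3 * X[:, 2]), 8.9)
        aics = []
        for m in range(4):
            est = NegativeBinomialRegressor().fit(X[:, :m], y)
            aics.append(est.aic_)
        assert aics[0] > aics[1] > aics[2] > aics[3]


class TestRateMode:
    def test_output_equal_input_gives_zero_intercept(self):
        rng = np.random.default_rng(0)
        t = rng.poisson(30, 4000) + 1
        fit, _ = fit_rate_mode(t.astype(float), t)
        assert fit.beta["intercept"] == pytest.approx(0.0, abs=1e-8)
        assert fit.mode == "rate"

    def test_doubling_exposure_shifts_intercept_by_log_two(self):
        rng = np.random.default_rng(1)
        t = rng.poisson(30, 4000) + 1
        y = t.astype(float)
        f1, _ = fit_rate_mode(y, t)
        f2, _ = fit_rate_mode(y, 2 * t)
        assert f2.beta["intercept"] - f1.beta["intercept"] == pytest.approx(
            -np.log(2), abs=1e-8)

    def test_recovers_programmed_rate(self):
        rng = np.random.default_rng(2)
        t = rng.poisson(30, 20_000) + 1
        y = nb_sample(rng, 1.7 * t, 8.9)
        fit, _ = fit_rate_mode(y, t)
        assert np.exp(fit.beta["intercept"]) == pytest.approx(1.7, rel=0.05)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            fit_rate_mode(np.array([1.0, 2.0]), np.array([0, 5]))

    def test_covariate_mode_with_free_log_t_matches_rate_mode(self):
        """When ln t is the only covariate and its coefficient is freely
        estimated, it lands near 1 and the fitted means agree with the
        offset parameterization."""
        rng = np.random.default_rng(3)
        t = rng.poisson(40, 20_000) + 1
        y = nb_sample(rng, 1.5 * t, 8.9)
        cov_fit, cov_est = fit_nb2(y, np.log(t)[:, None], mode="covariate")
        rate_fit, rate_est = fit_rate_mode(y, t)
        assert cov_fit.beta["x0"] == pytest.approx(1.0, abs=0.05)
        mu_cov = cov_est.predict(np.log(t)[:, None])
        mu_rate = rate_est.predict(np.empty((len(t), 0)), offset=np.log(t))
        assert np.abs(mu_cov / mu_rate - 1).max() < 0.1


class TestVarianceIdentity:
    def test_sample_variance_matches_quadratic_form(self):
        rng = np.random.default_rng(8)
        mu, theta = 40.0, 8.9
        y = nb_sample(rng, mu, theta, 200_000)
        expected = mu + mu**2 / theta
        assert y.var() == pytest.approx(expected, rel=0.03)


def bh_bruteforce(p):
    """Textbook step-up BH with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


class TestBHAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_computed_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    def test_empty_input(self):
        assert bh_adjust(np.array([])).size == 0

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_bruteforce_oracle(self, p):
        assert bh_adjust(np.array(p)) == pytest.approx(bh_bruteforce(p))


class TestCandidateDistributions:
    def test_poisson_mle_is_sample_mean(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(12.0, 5000)
        fits = fit_candidate_distributions(y)
        assert fits.poisson_lambda == pytest.approx(y.mean())

    def test_nb_fit_recovers_and_wins_qq(self):
        """On overdispersed counts the NB fit recovers (mu, theta) and its
        Q-Q curve deviates less from the observed quantiles than the
        Poisson or binomial fits."""
        rng = np.random.default_rng(1)
        y = nb_sample(rng, 41.6, 8.9, 20_000)
        t = np.full(len(y), 20)
        fits = fit_candidate_distributions(y, t)
        assert fits.nb_mu == pytest.approx(41.6, rel=0.05)
        assert fits.nb_theta == pytest.approx(8.9, rel=0.15)
        qq = fits.qq[fits.qq["percentile"].between(1, 99)]
        dev = {c: np.abs(qq[c] - qq["observed"]).max()
               for c in ("nb", "poisson", "binomial")}
        assert dev["nb"] < dev["poisson"] and dev["nb"] < dev["binomial"]

    def test_binomial_parameterization(self):
        y = np.array([10, 30])
        t = np.array([20, 20])
        fits = fit_candidate_distributions(y, t, min_size=1)
        assert fits.binomial_n == 40
        assert fits.binomial_p == pytest.approx(40 / 80)

    def test_constant_data_flagged_degenerate(self):
        fits = fit_candidate_distributions(np.full(500, 7))
        assert fits.degenerate

    def test_small_subset_warns_but_returns(self):
        with pytest.warns(RuntimeWarning):
            fits = fit_candidate_distributions(np.array([1.0, 2, 3, 4]))
        assert np.isfinite(fits.poisson_lambda)


class TestCalibration:
    def test_empty_input(self):
        table, ks = pvalue_calibration(np.array([]))
        assert table.empty and np.isnan(ks)

    def test_uniform_sample_tracks_diagonal(self):
        rng = np.random.default_rng(0)
        table, ks = pvalue_calibration(rng.uniform(size=10_000))
        assert ks < 0.02
        assert np.abs(table["observed"] - table["expected"]).max() < 0.03


def test_model_json_roundtrip(tmp_path):
    fit = NBFit(beta={"intercept": 1.2, "gc": 0.4}, theta=8.9,
                mode="covariate", log_likelihood=-123.4, aic=250.8,
                bic=260.1, iterations=12, converged=True)
    path = tmp_path / "model.json"
    fit.to_json(path)
    back = NBFit.from_json(path)
    assert back == fit
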