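import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import approx_fprime

from zoipanc.data_model import build_design_matrix
from zoipanc.fit import (
    ConvergenceError,
    ZOIPFitResult,
    _gamma_from_phi,
    _negloglik_grad,
    fit_intercept_only,
    fit_zoip,
    initialize_parameters,
    mean_ratio_table,
)
from zoipanc.simulate import SyntheticConfig, generate_pooled_dataset
from zoipanc.zoip import ZOIPParams, zoip_logpmf

N2000 = {"2011": 670, "2014": 440, "2017-18": 450, "2022": 440}


def test_analytic_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(300), rng.normal(size=(300, 2))])
    y = rng.poisson(np.exp(0.5 + 0.3 * X[:, 1]))
    theta = np.array([0.4, 0.2, -0.1, *_gamma_from_phi(0.2, 0.05)])
    f = lambda t: _negloglik_grad(t, y, X)[0]
    num = approx_fprime(theta, f, 1e-7)
    ana = _negloglik_grad(theta, y, X)[1]
    np.testing.assert_allclose(ana, num, rtol=1e-4, atol=1e-6)


class TestInitialValues:
    def test_pure_poisson_data_gives_floor_masses(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(2.0, size=3000)
        params = fit_intercept_only(y)
        assert params.phi0 <= 0.02
        assert params.phi1 <= 0.02

    def test_excess_zeros_push_phi0_up(self):
        y = np.array([0] * 90 + [1, 1, 2, 3, 4] * 2)
        params = fit_intercept_only(y)
        assert params.phi0 > 0.5

    def test_intercept_only_beta_is_log_mean(self):
        rng = np.random.default_rng(2)
        y = rng.poisson(2.5, size=500)
        design = _intercept_design(y)
        init = initialize_parameters(design)
        assert init.beta[0] == pytest.approx(np.log(y.mean()), abs=1e-6)


def _intercept_design(y):
    from zoipanc.data_model import DesignMatrix
    return DesignMatrix(y=np.asarray(y, dtype=int), X=np.ones((len(y), 1)),
                        column_labels=["Intercept"])


class TestOracleEquivalences:
    def test_restricted_fit_matches_poisson_glm(self):
        cfg = SyntheticConfig(seed=3, n_per_year=dict(N2000), phi0=0.0, phi1=0.0)
        df, _ = generate_pooled_dataset(cfg)
        design = build_design_matrix(df)
        beta0 = np.zeros(design.p)
        beta0[0] = np.log(design.y.mean())
        fit = fit_zoip(design, fix_inflation=True,
                       init=ZOIPParams(beta0, 0.0, 0.0), gtol=1e-10)
        glm = sm.GLM(design.y, design.X, family=sm.families.Poisson()).fit()
        assert fit.converged
        np.testing.assert_allclose(fit.params.beta, glm.params, atol=1e-6)

    def test_intercept_only_mle_matches_grid_search(self):
        y = np.array([0, 0, 0, 1, 1, 2, 3])
        counts = np.bincount(y)

        def grid_loglik(lam, p0, p1):
            # total log-likelihood over (lam, p0, p1) grids, broadcast
            ll = np.zeros(np.broadcast_shapes(lam.shape, p0.shape, p1.shape))
            for val, cnt in enumerate(counts):
                if cnt:
                    ll = ll + cnt * zoip_logpmf_grid(val, lam, p0, p1)
            return ll

        def zoip_logpmf_grid(val, lam, p0, p1):
            from scipy.special import gammaln
            p2 = 1.0 - p0 - p1
            base = np.log(p2) + val * np.log(lam) - lam - gammaln(val + 1)
            if val == 0:
                return np.log(p0 + p2 * np.exp(-lam))
            if val == 1:
                return np.log(p1 + p2 * lam * np.exp(-lam))
            return base

        def best_on(lams, p0s, p1s):
            L, P0, P1 = np.meshgrid(lams, p0s, p1s, indexing="ij", sparse=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = grid_loglik(L, P0, P1)
                ll = np.where(np.isfinite(ll), ll, -np.inf)
            valid = (P0 + P1 < 0.999)
            ll = np.where(np.broadcast_to(valid, ll.shape), ll, -np.inf)
            idx = np.unravel_index(np.argmax(ll), ll.shape)
            return lams[idx[0]], p0s[idx[1]], p1s[idx[2]]

        lam, p0, p1 = best_on(np.arange(0.05, 4.0, 0.01),
                              np.arange(0.0, 0.9, 0.01),
                              np.arange(0.0, 0.9, 0.01))
        lam, p0, p1 = best_on(
            np.arange(max(lam - 0.015, 1e-3), lam + 0.015, 1e-3),
            np.arange(max(p0 - 0.015, 0.0), min(p0 + 0.015, 0.95), 1e-3),
            np.arange(max(p1 - 0.015, 0.0), min(p1 + 0.015, 0.95), 1e-3))

        mle = fit_intercept_only(y)
        assert np.exp(mle.beta[0]) == pytest.approx(lam, abs=2e-3)
        assert mle.phi0 == pytest.approx(p0, abs=2e-3)
        assert mle.phi1 == pytest.approx(p1, abs=2e-3)

    def test_zoip_nests_poisson(self, standard_design, standard_fit):
        poisson_fit = fit_zoip(standard_design, fix_inflation=True)
        assert standard_fit.loglik >= poisson_fit.loglik


class TestFitBehaviour:
    def test_converged_fit_has_small_gradient(self, standard_fit):
        assert standard_fit.converged
        assert standard_fit.gradient_norm < 1e-5

    def test_vcov_symmetric_nonnegative_diagonal(self, standard_fit):
        V = standard_fit.vcov
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.all(np.diag(V) >= 0)

    def test_multistart_reaches_same_loglik(self, standard_design):
        rng = np.random.default_rng(17)
        base = initialize_parameters(standard_design)
        logliks = []
        for _ in range(5):
            beta = base.beta + rng.normal(scale=0.2, size=base.beta.shape)
            phi0 = float(np.clip(base.phi0 + rng.normal(scale=0.03), 0.01, 0.5))
            phi1 = float(np.clip(base.phi1 + rng.normal(scale=0.01), 0.005, 0.2))
            fit = fit_zoip(standard_design, init=ZOIPParams(beta, phi0, phi1),
                           compute_vcov=False)
            assert fit.converged
            logliks.append(fit.loglik)
        assert max(logliks) - min(logliks) < 1e-4

    def test_too_few_observations_rejected(self):
        y = np.array([0, 1, 2])
        design = _intercept_design(y)
        design.X = np.column_stack([design.X, np.eye(3)])
        design.column_labels = ["Intercept", "a", "b", "c"]
        with pytest.raises(ValueError, match="n > p"):
            fit_zoip(design)


@pytest.fixture(scope="module")
def simulation_study():
    """200 replicate fits at n=2000 under the published generating truth."""
    estimates, ses = [], []
    for s in range(200):
        cfg = SyntheticConfig(seed=5000 + s, n_per_year=dict(N2000))
        df, _ = generate_pooled_dataset(cfg)
        fit = fit_zoip(build_design_matrix(df))
        estimates.append(fit.estimates_full)
        ses.append(fit.se)
    truth = np.concatenate([SyntheticConfig().beta, [0.172, 0.011]])
    estimates, ses = np.array(estimates), np.array(ses)
    usable = np.isfinite(ses).all(axis=1)
    return estimates[usable], ses[usable], truth


class TestSamplingCalibration:
    def test_wald_coverage_of_coefficients(self, simulation_study):
        est, ses, truth = simulation_study
        cover = (np.abs(est - truth) <= 1.96 * ses).mean(axis=0)
        assert np.all(cover[:22] >= 0.90)
        assert np.all(cover[:22] <= 0.99)

    def test_reported_se_tracks_monte_carlo_sd(self, simulation_study):
        est, ses, truth = simulation_study
        ratio = ses.mean(axis=0)[:22] / est.std(axis=0)[:22]
        assert np.all(np.abs(ratio - 1) < 0.15)


class TestMeanRatioTable:
    def _toy_fit(self, beta, labels):
        k = len(beta) + 2
        return ZOIPFitResult(
            params=ZOIPParams(np.asarray(beta), 0.172, 0.011),
            vcov=np.eye(k) * 1e-4, loglik=0.0, converged=True, n_iter=1,
            gradient_norm=0.0, column_labels=list(labels))

    def test_exp_of_estimate_printed_precision(self):
        fit = self._toy_fit([-0.523, 0.618, 0.0], ["rural", "higher", "null"])
        rows = {r.label: r for r in mean_ratio_table(fit)}
        assert round(rows["rural"].mean_ratio, 3) == 0.593
        assert round(rows["higher"].mean_ratio, 3) == 1.855
        assert rows["null"].mean_ratio == 1.0

    def test_inflation_rows_have_no_ratio(self):
        fit = self._toy_fit([0.1], ["Intercept"])
        rows = mean_ratio_table(fit)
        assert [r.label for r in rows[-2:]] == ["phi0", "phi1"]
        assert rows[-1].mean_ratio is None and rows[-2].mean_ratio is None
        assert all(0 <= r.p_value <= 1 for r in rows)

    def test_rejects_nonconverged_fit(self):
        fit = self._toy_fit([0.1], ["Intercept"])
        fit.converged = False
        with pytest.raises(ConvergenceError):
            mean_ratio_table(fit)
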