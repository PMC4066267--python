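"""Likelihood and fitting tests for the PLME/NBLME/ZINBLME families.

The key oracle: the adaptive Gauss-Hermite marginal likelihood must agree
with dense-grid numerical integration over the random intercept.
"""

import numpy as np
import pytest
from scipy.stats import nbinom, norm, poisson

from vmlong.count_models import (
    FAMILIES,
    ModelSpec,
    aic,
    fit,
    marginal_loglik,
    wald,
    wald_linear,
)
from vmlong.synthetic import simulate_from_model


def grid_marginal_loglik(X, offset, subjects, y, family, params, n_grid=20001, span=10.0):
    """Independent oracle: trapezoid integration over the random intercept."""
    p = X.shape[1]
    beta, sigma = params[:p], params[p]
    k = params[p + 1] if family != "PLME" else None
    pi = params[p + 2] if family == "ZINBLME" else 0.0
    grid = np.linspace(-span * sigma, span * sigma, n_grid)
    log_phi = norm.logpdf(grid, 0.0, sigma)
    total = 0.0
    for s in np.unique(subjects):
        m = subjects == s
        eta = X[m] @ beta + offset[m]
        mu = np.exp(eta[:, None] + grid[None, :])
        if family == "PLME":
            lf = poisson.logpmf(y[m][:, None], mu)
        else:
            lf = nbinom.logpmf(y[m][:, None], k, k / (k + mu))
            if family == "ZINBLME":
                lf = np.where(
                    y[m][:, None] == 0,
                    np.logaddexp(np.log(pi), np.log1p(-pi) + lf),
                    np.log1p(-pi) + lf,
                )
        # integrate in log space to survive tiny joint densities
        lj = lf.sum(axis=0) + log_phi
        peak = lj.max()
        total += peak + np.log(np.trapezoid(np.exp(lj - peak), grid))
    return total


def _random_instance(rng, n_subjects=6, n_visits=3):
    subjects = np.repeat(np.arange(n_subjects), n_visits)
    n = len(subjects)
    X = np.c_[np.ones(n), rng.integers(0, 2, n_subjects)[subjects].astype(float)]
    offset = np.log(rng.lognormal(np.log(5000), 0.4, n))
    beta = np.array([rng.uniform(-8, -5), rng.uniform(-1, 1)])
    sigma = rng.uniform(0.2, 1.0)
    k = rng.uniform(0.5, 3.0)
    pi = rng.uniform(0.05, 0.4)
    y = simulate_from_model(X, offset, subjects, beta, sigma, k=k, pi=pi, rng=rng)
    return X, offset, subjects, y, beta, sigma, k, pi


class TestMarginalLoglik:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_agrees_with_grid_integration(self, family):
        rng = np.random.default_rng(101)
        for _ in range(7):
            X, offset, subjects, y, beta, sigma, k, pi = _random_instance(rng)
            params = {
                "PLME": np.r_[beta, sigma],
                "NBLME": np.r_[beta, sigma, k],
                "ZINBLME": np.r_[beta, sigma, k, pi],
            }[family]
            spec = ModelSpec(family, X, offset, subjects)
            got = marginal_loglik(spec, params, y)
            want = grid_marginal_loglik(X, offset, subjects, y, family, params)
            assert got == pytest.approx(want, abs=1e-6)

    def test_degenerate_sigma_is_independent_nb(self):
        rng = np.random.default_rng(5)
        X, offset, subjects, y, beta, _, k, _ = _random_instance(rng)
        spec = ModelSpec("NBLME", X, offset, subjects)
        got = marginal_loglik(spec, np.r_[beta, 0.0, k], y)
        want = nbinom.logpmf(y, k, k / (k + np.exp(X @ beta + offset))).sum()
        assert got == pytest.approx(want, abs=1e-8)

    def test_zinb_single_zero_observation(self):
        # one subject, one observation y=0: log(pi + (1-pi) NB(0)) marginalized
        X = np.array([[1.0]])
        offset = np.array([np.log(1000.0)])
        subjects = np.array([0])
        y = np.array([0])
        params = np.array([-5.0, 0.6, 1.5, 0.3])
        spec = ModelSpec("ZINBLME", X, offset, subjects)
        got = marginal_loglik(spec, params, y)
        want = grid_marginal_loglik(X, offset, subjects, y, "ZINBLME", params)
        assert got == pytest.approx(want, abs=1e-6)

    def test_pi_near_one_with_positive_counts_diverges(self):
        X = np.ones((2, 1))
        offset = np.full(2, np.log(100.0))
        subjects = np.array([0, 0])
        y = np.array([5, 3])
        spec = ModelSpec("ZINBLME", X, offset, subjects)
        ll = [
            marginal_loglik(spec, np.array([-2.0, 0.5, 1.0, pi]), y)
            for pi in (0.5, 0.9, 0.999999)
        ]
        assert ll[0] > ll[1] > ll[2]
        assert ll[2] < -20  # log(1-pi) term dominates

    def test_nesting_nblme_is_zinb_at_zero_pi(self):
        rng = np.random.default_rng(6)
        X, offset, subjects, y, beta, sigma, k, _ = _random_instance(rng)
        nb = marginal_loglik(ModelSpec("NBLME", X, offset, subjects), np.r_[beta, sigma, k], y)
        zi = marginal_loglik(
            ModelSpec("ZINBLME", X, offset, subjects), np.r_[beta, sigma, k, 0.0], y
        )
        assert nb == pytest.approx(zi, abs=1e-10)

    def test_parameter_domain_enforced(self):
        X = np.ones((2, 1))
        spec = ModelSpec("NBLME", X, np.zeros(2), np.array([0, 1]))
        with pytest.raises(ValueError):
            spec.unpack(np.array([0.0, -0.1, 1.0]))  # sigma < 0
        with pytest.raises(ValueError):
            spec.unpack(np.array([0.0, 0.5, -1.0]))  # k <= 0


class TestFit:
    def test_nblme_recovers_truth_within_mc_error(self):
        rng = np.random.default_rng(88)
        n_subjects = 60
        subjects = np.repeat(np.arange(n_subjects), 4)
        n = len(subjects)
        X = np.c_[np.ones(n), (np.arange(n_subjects) % 2)[subjects].astype(float)]
        offset = np.log(rng.lognormal(np.log(7548), 0.42, n))
        beta = np.array([-6.0, 0.8])
        y = simulate_from_model(X, offset, subjects, beta, 0.5, k=1.0, rng=rng)
        spec = ModelSpec("NBLME", X, offset, subjects)
        f = fit(spec, y, n_restarts=1, restart_seed=0)
        assert f.converged
        # 3 Monte-Carlo SEs of the group coefficient
        assert abs(f.beta[1] - 0.8) < 3 * f.se[1]
        assert f.dispersion == pytest.approx(1.0, rel=0.6)
        assert f.sigma_b == pytest.approx(0.5, rel=0.6)

    def test_plme_loses_to_nblme_on_overdispersed_data(self):
        rng = np.random.default_rng(13)
        subjects = np.repeat(np.arange(40), 4)
        n = len(subjects)
        X = np.ones((n, 1))
        offset = np.full(n, np.log(5000.0))
        y = simulate_from_model(X, offset, subjects, [-5.0], 0.4, k=0.5, rng=rng)
        plme = fit(ModelSpec("PLME", X, offset, subjects), y, n_restarts=0, compute_se=False)
        nblme = fit(ModelSpec("NBLME", X, offset, subjects), y, n_restarts=0, compute_se=False)
        assert nblme.aic < plme.aic

    def test_offset_contract(self):
        # scaling all totals by c shifts the intercept by -log c; the group
        # coefficient is unchanged
        rng = np.random.default_rng(21)
        subjects = np.repeat(np.arange(30), 3)
        n = len(subjects)
        X = np.c_[np.ones(n), (np.arange(30) % 2)[subjects].astype(float)]
        offset = np.log(rng.lognormal(np.log(5000), 0.3, n))
        y = simulate_from_model(X, offset, subjects, [-5.0, 0.6], 0.4, k=2.0, rng=rng)
        c = 10.0
        f1 = fit(ModelSpec("NBLME", X, offset, subjects), y, n_restarts=0, compute_se=False)
        f2 = fit(
            ModelSpec("NBLME", X, offset + np.log(c), subjects), y,
            n_restarts=0, compute_se=False,
        )
        assert f2.beta[0] == pytest.approx(f1.beta[0] - np.log(c), abs=1e-3)
        assert f2.beta[1] == pytest.approx(f1.beta[1], abs=1e-3)

    def test_all_zero_counts_zinb_hits_boundary(self):
        subjects = np.repeat(np.arange(4), 3)
        n = len(subjects)
        X = np.ones((n, 1))
        offset = np.full(n, np.log(1000.0))
        y = np.zeros(n, dtype=int)
        f = fit(ModelSpec("ZINBLME", X, offset, subjects), y, n_restarts=0, compute_se=False)
        # a degenerate all-zero fit must be flagged, never silently "clean"
        assert f.boundary or not f.converged or f.zi_prob > 0.9

    def test_rank_deficient_design_rejected(self):
        X = np.c_[np.ones(4), np.ones(4)]
        with pytest.raises(ValueError, match="rank"):
            ModelSpec("PLME", X, np.zeros(4), np.array([0, 0, 1, 1]))


class TestAICAndWald:
    def test_aic_formula(self):
        from vmlong.count_models import ModelFit

        f = ModelFit(
            family="NBLME", beta=np.zeros(2), sigma_b=0.1, dispersion=1.0,
            zi_prob=None, loglik=-100.0, n_obs=10, n_params=4,
            se=np.full(4, 0.1), converged=True,
        )
        assert aic(f) == pytest.approx(208.0)
        f.n_params = 5
        assert aic(f) == pytest.approx(210.0)

    def test_parameter_counts_per_family(self):
        X = np.c_[np.ones(4), [0, 0, 1, 1.0]]
        subjects = np.array([0, 0, 1, 1])
        for family, extra in (("PLME", 1), ("NBLME", 2), ("ZINBLME", 3)):
            spec = ModelSpec(family, X, np.zeros(4), subjects)
            assert spec.n_params == 2 + extra

    def test_wald_normal_quantiles(self):
        from vmlong.count_models import ModelFit

        f = ModelFit(
            family="NBLME", beta=np.array([0.0, 1.96]), sigma_b=0.1, dispersion=1.0,
            zi_prob=None, loglik=-10.0, n_obs=10, n_params=4,
            se=np.array([1.0, 1.0, 0.1, 0.1]), converged=True,
        )
        est, lo, hi, p = wald(f, 0)
        assert (lo, hi) == (pytest.approx(-1.96, abs=1e-3), pytest.approx(1.96, abs=1e-3))
        assert p == pytest.approx(1.0)
        est, lo, hi, p = wald(f, 1)
        assert p == pytest.approx(0.05, abs=1e-3)
        assert hi - est == pytest.approx(est - lo)  # symmetric CI

    def test_wald_linear_matches_single_coef(self):
        rng = np.random.default_rng(9)
        subjects = np.repeat(np.arange(20), 3)
        n = len(subjects)
        X = np.c_[np.ones(n), (np.arange(20) % 2)[subjects].astype(float)]
        offset = np.full(n, np.log(3000.0))
        y = simulate_from_model(X, offset, subjects, [-5.0, 0.5], 0.3, k=2.0, rng=rng)
        f = fit(ModelSpec("NBLME", X, offset, subjects), y, n_restarts=0)
        assert f.cov is not None
        direct = wald(f, 1)
        via_contrast = wald_linear(f, [0.0, 1.0])
        assert direct == pytest.approx(via_contrast, rel=1e-9)
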