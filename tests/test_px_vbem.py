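"""Variational fit: ELBO correctness, monotone ascent, oracle agreement."""

import numpy as np
import pytest
from scipy.optimize import minimize

from sumtwas import px_vbem
from sumtwas.model_core import (
    GeneSummaryData,
    LatentEffects,
    ModelParams,
    exact_marginal_loglik,
    loglik_kernel,
)
from sumtwas.px_vbem import (
    VariationalPosterior,
    elbo,
    fit,
    reduce_expansion,
    update_parameters,
    update_posterior,
)

from conftest import model_draw


def numerical_mle(data, null_model=False, starts=((-4, 0), (-1, 0.5), (0, -0.5))):
    """Joint maximization of the exact Gaussian marginal (test oracle)."""

    def nll(x):
        s2 = max(np.exp(x[0]), 1e-10)
        a = 0.0 if null_model else x[1]
        try:
            return -exact_marginal_loglik(data, ModelParams(s2, a))
        except np.linalg.LinAlgError:
            return 1e12

    best = None
    for x0 in starts:
        res = minimize(
            nll,
            list(x0),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return np.exp(best.x[0]), (0.0 if null_model else best.x[1])


class TestElbo:
    def test_hand_computed_scalar_case(self):
        d = GeneSummaryData("g", [0.0], [0.0], [[1.0]], [[1.0]])
        q = VariationalPosterior([0.0], [0.5])
        p = ModelParams(1.0, 0.0, 1.0)
        expected = (
            -0.5 * 0.5  # eQTL quadratic: tau^2/2 * E[g^2]
            - 0.5 * 0.5  # prior quadratic: E[g^2] / (2 sigma2)
            - 0.5 * np.log(2 * np.pi)  # prior normalizer
            + 0.5 * np.log(2 * np.pi * 0.5 * np.e)  # entropy
        )
        assert elbo(d, p, q) == pytest.approx(expected)

    @pytest.mark.parametrize("rho", [0.0, 0.6])
    def test_lower_bounds_marginal(self, rng, rho):
        d = model_draw(rng, m=4, rho=rho)
        p = ModelParams(0.7, 0.4, 1.1)
        for _ in range(5):
            q = VariationalPosterior(
                rng.standard_normal(4), rng.uniform(0.05, 2.0, 4)
            )
            assert elbo(d, p, q) <= exact_marginal_loglik(
                d, p, drop_constant=True
            ) + 1e-9

    def test_scalar_optimum_attains_marginal(self, rng):
        """Mean-field is exact at m=1: optimized ELBO equals the marginal."""
        d = model_draw(rng, m=1)
        fr = fit(d, tol=1e-12)
        assert fr.elbo == pytest.approx(
            exact_marginal_loglik(d, fr.params, drop_constant=True), abs=1e-8
        )

    def test_rejects_nonpositive_variance(self, small_data, default_params):
        with pytest.raises(ValueError):
            VariationalPosterior([0.0] * 4, [1.0, 1.0, 0.0, 1.0])


class TestUpdatePosterior:
    def test_identity_ld_fixed_point(self, rng):
        """With R1=R2=I the fixed point is the stated closed form."""
        m = 3
        d = GeneSummaryData(
            "g",
            rng.standard_normal(m),
            rng.standard_normal(m),
            np.eye(m),
            np.eye(m),
        )
        p = ModelParams(0.8, 0.6, 1.0)
        q = VariationalPosterior(np.zeros(m), np.ones(m))
        q = update_posterior(d, p, q)
        expected = (d.eqtl_z + 0.6 * d.gwas_z) / (1 + 0.6**2 + 1 / 0.8)
        np.testing.assert_allclose(q.mu, expected, atol=1e-12)

    def test_coordinate_update_is_exact_conditional(self, rng):
        """Each updated factor matches the 1-d conditional of the kernel."""
        d = model_draw(rng, m=4, rho=0.5)
        p = ModelParams(0.7, 0.5, 1.2)
        q0 = VariationalPosterior(rng.standard_normal(4), np.ones(4))
        q1 = update_posterior(d, p, q0)
        # recompute coordinate 0 by maximizing the kernel in gamma_0 with the
        # other coordinates at their pre-update means (Gauss-Seidel order)
        grid = np.linspace(-6, 6, 20001)
        vals = []
        for g0 in grid:
            g = np.array([g0, q0.mu[1], q0.mu[2], q0.mu[3]])
            vals.append(loglik_kernel(d, LatentEffects(g), p))
        vals = np.asarray(vals)
        mode = grid[np.argmax(vals)]
        assert q1.mu[0] == pytest.approx(mode, abs=2e-3)
        # conditional precision from the quadratic coefficient
        prec = p.tau**2 + p.alpha_prime**2 + 1 / p.sigma2_gamma
        assert q1.s2[0] == pytest.approx(1 / prec)

    def test_null_ignores_gwas(self, rng):
        d = model_draw(rng, m=3, rho=0.4)
        d2 = GeneSummaryData(
            "g", d.eqtl_z, -3.0 * d.gwas_z, d.ld_eqtl, np.eye(3)
        )
        p = ModelParams(0.5, 0.0, 1.0, null_model=True)
        q = VariationalPosterior(np.zeros(3), np.ones(3))
        np.testing.assert_allclose(
            update_posterior(d, p, q).mu, update_posterior(d2, p, q).mu
        )


class TestUpdateParameters:
    def test_mean_zero_posterior_sets_sigma2(self, small_data):
        q = VariationalPosterior(np.zeros(4), np.full(4, 0.37))
        p = update_parameters(small_data, ModelParams(1.0), q)
        assert p.sigma2_gamma == pytest.approx(0.37)

    def test_returned_parameters_are_local_maximum(self, rng):
        d = model_draw(rng, m=4, rho=0.5)
        q = VariationalPosterior(rng.standard_normal(4), rng.uniform(0.1, 1, 4))
        p = update_parameters(d, ModelParams(0.5, 0.2, 1.0), q)
        base = elbo(d, p, q)
        for eps in (1e-3, -1e-3):
            assert elbo(d, ModelParams(p.sigma2_gamma + eps, p.alpha_prime, p.tau), q) < base
            assert elbo(d, ModelParams(p.sigma2_gamma, p.alpha_prime + eps, p.tau), q) < base
            assert elbo(d, ModelParams(p.sigma2_gamma, p.alpha_prime, p.tau + eps), q) < base

    def test_null_constraint_pins_alpha(self, rng):
        d = model_draw(rng, m=3)
        q = VariationalPosterior(rng.standard_normal(3), np.ones(3))
        p = update_parameters(
            d, ModelParams(0.5, 0.0, 1.0, null_model=True), q
        )
        assert p.alpha_prime == 0.0


class TestReduceExpansion:
    def test_identity_at_tau_one(self):
        p = ModelParams(0.3, 0.7, 1.0)
        r = reduce_expansion(p)
        assert (r.sigma2_gamma, r.alpha_prime, r.tau) == (0.3, 0.7, 1.0)

    def test_stated_map(self):
        r = reduce_expansion(ModelParams(0.25, 1.0, 2.0))
        assert r.sigma2_gamma == pytest.approx(1.0)
        assert r.alpha_prime == pytest.approx(0.5)
        assert r.tau == 1.0

    def test_marginal_invariant(self, rng):
        d = model_draw(rng, m=3, rho=0.5)
        p = ModelParams(0.4, 0.8, 1.7)
        assert exact_marginal_loglik(d, p) == pytest.approx(
            exact_marginal_loglik(d, reduce_expansion(p)), abs=1e-9
        )

    def test_degenerate_tau_floors_variance(self):
        r = reduce_expansion(ModelParams(0.5, 0.7, 0.0))
        assert r.sigma2_gamma == pytest.approx(px_vbem.SIGMA2_FLOOR)
        assert r.alpha_prime == 0.7


class TestFit:
    def test_scalar_sigma2_matches_grid_search(self, rng):
        d = model_draw(rng, m=1, sigma2=1.5, alpha=0.0)
        fr = fit(d, null_model=True, tol=1e-12)
        grid = np.exp(np.linspace(np.log(1e-6), np.log(50), 20000))
        lls = [
            exact_marginal_loglik(d, ModelParams(s, 0.0)) for s in grid
        ]
        best = grid[int(np.argmax(lls))]
        assert fr.params.sigma2_gamma == pytest.approx(best, abs=1e-3)

    @pytest.mark.parametrize("m", [2, 3, 5])
    def test_matches_numerical_mle_uncorrelated_ld(self, m):
        """Mean-field is exact for diagonal LD, so fit = exact MLE."""
        rng = np.random.default_rng(100 + m)
        d = model_draw(rng, m=m, sigma2=2.0, alpha=0.6, rho=0.0)
        fr = fit(d, tol=1e-12)
        s2_mle, a_mle = numerical_mle(d)
        assert fr.params.sigma2_gamma == pytest.approx(s2_mle, abs=1e-2)
        assert fr.params.alpha_prime == pytest.approx(a_mle, abs=1e-2)

    def test_no_signal_shrinks_to_floor(self):
        m = 4
        d = GeneSummaryData(
            "g", np.zeros(m), np.zeros(m), np.eye(m), np.eye(m)
        )
        fr = fit(d)
        assert fr.params.alpha_prime == 0.0
        assert fr.params.sigma2_gamma == pytest.approx(1e-8)

    @pytest.mark.parametrize("use_px", [True, False])
    def test_trace_monotone(self, rng, use_px):
        d = model_draw(rng, m=20, rho=0.8)
        fr = fit(d, use_px=use_px)
        assert np.all(np.diff(fr.elbo_trace) >= -1e-8)

    def test_px_not_below_frozen_tau(self, rng):
        d = model_draw(rng, m=30, rho=0.8)
        fr_px = fit(d)
        fr_plain = fit(d, use_px=False)
        assert fr_px.elbo >= fr_plain.elbo - 1e-6

    def test_px_accelerates_on_correlated_ld(self, rng):
        """Expansion cuts the median iteration count at rho=0.8."""
        it_px, it_plain = [], []
        for _ in range(15):
            d = model_draw(rng, m=60, sigma2=0.05, alpha=0.3, rho=0.8)
            it_px.append(fit(d).n_iter)
            it_plain.append(fit(d, use_px=False).n_iter)
        assert np.median(it_px) < np.median(it_plain)

    def test_deterministic(self, rng):
        d = model_draw(rng, m=10, rho=0.5)
        a, b = fit(d), fit(d)
        assert a.elbo == b.elbo
        np.testing.assert_array_equal(a.posterior.mu, b.posterior.mu)

    def test_reduced_elbo_equals_last_trace_value(self, rng):
        """The expansion reduction leaves the reported ELBO unchanged."""
        d = model_draw(rng, m=6, rho=0.5)
        fr = fit(d)
        assert fr.elbo == pytest.approx(fr.elbo_trace[-1], abs=1e-8)
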