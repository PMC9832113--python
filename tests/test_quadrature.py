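"""Gauss-Hermite rules, product grids, posterior modes, adaptive transform."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import mimicgsem as mg
from mimicgsem.likelihood import MarginalLikelihood, ParameterVector
from mimicgsem.quadrature import AdaptiveState, adapt_rule, ghq_rule, product_grid


def normal_moment(k: int) -> float:
    """E[X^k] for X ~ N(0,1): (k-1)!! for even k, 0 for odd."""
    if k % 2:
        return 0.0
    out = 1.0
    for m in range(k - 1, 0, -2):
        out *= m
    return out


class TestRule:
    def test_q1_is_mean_point(self):
        r = ghq_rule(1)
        assert r.abscissas == pytest.approx([0.0])
        assert r.weights == pytest.approx([1.0])

    def test_q_below_one_rejected(self):
        with pytest.raises(ValueError):
            ghq_rule(0)

    def test_q2_second_moment(self):
        r = ghq_rule(2)
        assert float(r.weights @ r.abscissas**2) == pytest.approx(1.0, abs=1e-12)

    def test_q5_eighth_moment_vs_brute_force(self):
        # independent oracle: trapezoid integration of x^8 phi(x) on [-10, 10]
        x = np.linspace(-10, 10, 1_000_001)
        brute = np.trapezoid(x**8 * norm.pdf(x), x)
        r = ghq_rule(5)
        assert float(r.weights @ r.abscissas**8) == pytest.approx(brute, rel=1e-8)
        assert brute == pytest.approx(105.0, rel=1e-10)

    @pytest.mark.parametrize("q", range(2, 11))
    def test_polynomial_exactness_up_to_2q_minus_1(self, q):
        r = ghq_rule(q)
        for k in range(2 * q):
            got = float(r.weights @ r.abscissas**k)
            want = normal_moment(k)
            # odd moments vanish by cancellation; scale roundoff by the
            # magnitude of the cancelled terms
            scale = float(r.weights @ np.abs(r.abscissas) ** k)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-10 * max(1.0, scale))

    @given(st.integers(min_value=1, max_value=25))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_weights_normalized_and_symmetric(self, q):
        r = ghq_rule(q)
        assert float(r.weights.sum()) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(r.abscissas, -r.abscissas[::-1], atol=1e-12)
        np.testing.assert_allclose(r.weights, r.weights[::-1], atol=1e-14)


class TestProductGrid:
    def test_grid_size(self):
        g = product_grid(ghq_rule(3), 2)
        assert g.nodes.shape == (9, 2)

    @pytest.mark.parametrize("q,r", [(2, 1), (3, 2), (4, 3), (7, 2)])
    def test_weights_sum_to_one(self, q, r):
        g = product_grid(ghq_rule(q), r)
        assert float(g.weights.sum()) == pytest.approx(1.0, abs=1e-12)

    def test_bivariate_second_moment(self):
        g = product_grid(ghq_rule(2), 2)
        val = float(g.weights @ (g.nodes**2).sum(axis=1))
        assert val == pytest.approx(2.0, abs=1e-12)


class TestPosteriorMode:
    def test_zero_loadings_leave_prior(self, one_latent_spec):
        layout = mg.param_layout(one_latent_spec)
        theta = ParameterVector.from_dict(layout, {
            "intercept:y1": 0.3, "loading:y2": 0.0, "loading:y3": 0.0, "lnsd:trait": 0.0,
        })
        # anchor loading is fixed at 1, so drop its indicator from the data
        state = mg.locate_posterior_mode(
            theta, {"y1": np.nan, "y2": 1.0, "y3": 0.0}, one_latent_spec
        )
        assert state.mode == pytest.approx([0.0], abs=1e-8)
        assert state.curvature == pytest.approx(np.eye(1), abs=1e-8)

    def test_positive_indicator_pushes_mode_up(self, one_latent_spec):
        layout = mg.param_layout(one_latent_spec)
        theta = ParameterVector.from_dict(layout, {
            "loading:y2": 0.0, "loading:y3": 0.0, "lnsd:trait": 0.0,
        })
        state = mg.locate_posterior_mode(
            theta, {"y1": 1.0, "y2": np.nan, "y3": np.nan}, one_latent_spec
        )
        assert state.mode[0] > 0

    def test_mode_matches_grid_search(self, one_latent_spec):
        # brute-force 1-D oracle: maximize log phi(v) + loglik over a fine grid
        layout = mg.param_layout(one_latent_spec)
        theta = ParameterVector.from_dict(layout, {
            "loading:y2": 1.5, "loading:y3": 0.0, "lnsd:trait": 0.0,
        })
        y = {"y1": 1.0, "y2": 0.0, "y3": np.nan}
        v = np.arange(-6, 6, 1e-4)
        obj = norm.logpdf(v)
        for name, lam in [("y1", 1.0), ("y2", 1.5)]:
            z = lam * v
            p = 1 / (1 + np.exp(-z))
            obj += y[name] * np.log(p) + (1 - y[name]) * np.log(1 - p)
        state = mg.locate_posterior_mode(theta, y, one_latent_spec)
        assert state.mode[0] == pytest.approx(v[np.argmax(obj)], abs=2e-4)


class TestAdaptRule:
    def test_identity_state_is_identity(self):
        g = product_grid(ghq_rule(5), 2)
        ad = adapt_rule(g, AdaptiveState(np.zeros(2), np.eye(2)))
        np.testing.assert_allclose(ad.nodes, g.nodes, atol=1e-12)
        np.testing.assert_allclose(ad.weights, g.weights, atol=1e-12)

    def test_prior_normalization_reproduced(self):
        # integrand f == 1: the adaptive rule integrates phi to 1 once the
        # rule resolves the Gaussian ratio (converged by q=21 here)
        g = product_grid(ghq_rule(21), 2)
        state = AdaptiveState(np.array([0.4, -0.2]), np.array([[0.5, 0.1], [0.1, 0.8]]))
        ad = adapt_rule(g, state)
        assert float(ad.weights.sum()) == pytest.approx(1.0, abs=1e-8)
        # and exactly, for any q, when the state is the prior itself
        g5 = product_grid(ghq_rule(5), 2)
        ad5 = adapt_rule(g5, AdaptiveState(np.zeros(2), np.eye(2)))
        assert float(ad5.weights.sum()) == pytest.approx(1.0, abs=1e-12)

    def test_non_pd_curvature_rejected(self):
        g = product_grid(ghq_rule(3), 2)
        with pytest.raises(np.linalg.LinAlgError):
            adapt_rule(g, AdaptiveState(np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]])))

    def test_sqrt_choice_does_not_change_likelihood(self, moderate_spec, moderate_theta,
                                                    moderate_data):
        """Cholesky vs symmetric square root of tau: same LL to 1e-10.

        The identity is exact for the integral; the tensor grid inherits it
        once the rule is converged, so the check runs at q=15.
        """
        ev = MarginalLikelihood(moderate_spec, moderate_data, q=15, adaptive=True)
        tv = moderate_theta.values
        ll_chol = ev.loglik(tv)

        mu, C, _ = ev.posterior_modes(tv)
        tau = np.einsum("nij,nkj->nik", C, C)
        w, V = np.linalg.eigh(tau)
        S = np.einsum("nij,nj,nkj->nik", V, np.sqrt(w), V)  # symmetric sqrt
        A = ev._base_nodes
        alpha = mu[:, None, :] + np.einsum("nrs,ks->nkr", S, A)
        logdet = 0.5 * np.sum(np.log(w), axis=1)
        ev._nodes = alpha
        ev._logw = (
            ev._base_logw[None, :] + logdet[:, None]
            + 0.5 * np.sum(A * A, axis=1)[None, :] - 0.5 * np.sum(alpha**2, axis=2)
        )
        ll_sym = ev.loglik(tv, refresh=False)
        assert ll_sym == pytest.approx(ll_chol, abs=1e-10)

    def test_adaptive_matches_dense_rule_one_latent(self, one_latent_spec, one_latent_theta):
        """q=7 adaptive vs q=30 plain agree to 1e-6 relative on a small model."""
        data = mg.simulate_children(
            mg.SimulationConfig(n=150, seed=9, true_params=one_latent_theta,
                                covariate_marginals={}),
            one_latent_spec,
        )
        tv = one_latent_theta.values
        ll_ad = MarginalLikelihood(one_latent_spec, data, q=7, adaptive=True).loglik(tv)
        ll_pl = MarginalLikelihood(one_latent_spec, data, q=30, adaptive=False).loglik(tv)
        assert ll_ad == pytest.approx(ll_pl, rel=1e-6)


def test_monotone_stabilization(moderate_spec, moderate_theta, moderate_data):
    """|LL(q) - LL(q+2)| shrinks with q for both rules on fixed data."""
    tv = moderate_theta.values
    for adaptive in (True, False):
        lls = {
            q: MarginalLikelihood(moderate_spec, moderate_data, q=q,
                                  adaptive=adaptive).loglik(tv)
            for q in (3, 5, 7, 9, 11)
        }
        gaps = [abs(lls[q] - lls[q + 2]) for q in (3, 5, 7, 9)]
        assert all(g2 <= g1 + 1e-12 for g1, g2 in zip(gaps, gaps[1:]))
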