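"""Linear predictors, Bernoulli conditionals, and the quadrature marginal
log-likelihood against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import mimicgsem as mg
from mimicgsem.likelihood import (
    MarginalLikelihood, ParameterVector, conditional_loglik, inverse_link,
    linear_predictor, marginal_loglik,
)
from mimicgsem.model_spec import Covariate, Indicator, LatentVariable, ModelSpec
from conftest import MODERATE_MARGINALS


class TestInverseLink:
    @pytest.mark.parametrize(
        "link,z,expected",
        [
            ("logit", 0.0, 0.5),
            ("probit", 0.0, 0.5),
            ("cloglog", 0.0, 1.0 - np.exp(-1.0)),
            ("logit", 2.0, 1 / (1 + np.exp(-2.0))),
            ("probit", -1.3, norm.cdf(-1.3)),
        ],
    )
    def test_closed_forms(self, link, z, expected):
        assert inverse_link(link, z) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("link", ["logit", "probit", "cloglog"])
    def test_maps_reals_into_open_unit_interval(self, link):
        z = np.linspace(-40, 40, 401)
        p = inverse_link(link, z)
        assert np.all(p > 0) and np.all(p < 1)

    def test_symmetry_at_zero(self):
        # logit and probit are symmetric about 0.5 at z=0; cloglog is not
        assert inverse_link("logit", 0.0) == 0.5
        assert inverse_link("probit", 0.0) == 0.5
        assert inverse_link("cloglog", 0.0) != pytest.approx(0.5, abs=0.05)


class TestLinearPredictor:
    def test_all_zero_parameters_give_zero(self, moderate_spec):
        layout = mg.param_layout(moderate_spec)
        theta = ParameterVector(layout)  # anchors still fixed at 1
        lp = linear_predictor(
            theta, {"wealth_index": "poor", "breastfeeding": "no"},
            np.zeros(2), moderate_spec,
        )
        assert lp.z == pytest.approx(np.zeros(6), abs=1e-14)

    def test_intercept_shift_is_local_and_additive(self, moderate_spec, moderate_theta):
        x = {"wealth_index": "rich", "breastfeeding": "yes"}
        v = np.array([0.7, -0.4])
        base = linear_predictor(moderate_theta, x, v, moderate_spec)
        bumped = moderate_theta.copy()
        bumped["intercept:cough"] += 1.5
        after = linear_predictor(bumped, x, v, moderate_spec)
        delta = after.z - base.z
        j = list(base.indicator_names).index("cough")
        expected = np.zeros(6)
        expected[j] = 1.5
        assert delta == pytest.approx(expected, abs=1e-12)

    def test_matches_symbolic_composition(self, moderate_spec, moderate_theta):
        """Oracle: hand-composed affine expression via sympy."""
        import sympy as sp

        v1, v2 = sp.symbols("v1 v2")
        t = moderate_theta
        sd1 = sp.exp(t["lnsd:malnutrition"])
        sd2 = sp.exp(t["lnsd:morbidity"])
        beta = t["struct:morbidity<-malnutrition"]
        eta1 = t["reg:malnutrition<-wealth_index=rich"] + sd1 * v1
        eta2 = t["reg:morbidity<-breastfeeding=yes"] + beta * eta1 + sd2 * v2
        lam = {"stunting": 1, "wasting": t["loading:wasting"],
               "underweight": t["loading:underweight"], "diarrhea": 1,
               "cough": t["loading:cough"], "fever": t["loading:fever"]}
        parent = {"stunting": eta1, "wasting": eta1, "underweight": eta1,
                  "diarrhea": eta2, "cough": eta2, "fever": eta2}
        x = {"wealth_index": "rich", "breastfeeding": "yes"}
        point = {v1: 1.0, v2: -1.0}
        lp = linear_predictor(moderate_theta, x, np.array([1.0, -1.0]), moderate_spec)
        for j, name in enumerate(lp.indicator_names):
            sym = t[f"intercept:{name}"] + lam[name] * parent[name]
            want = float(sp.N(sym.subs(point)))
            assert lp.z[j] == pytest.approx(want, abs=1e-10)


class TestConditionalLoglik:
    def test_single_logit_indicator_at_zero(self):
        assert conditional_loglik([1.0], [0.0], "logit") == pytest.approx(np.log(0.5))

    def test_all_missing_is_empty_sum(self):
        assert conditional_loglik([np.nan, np.nan], [1.0, -2.0], "logit") == 0.0

    def test_symmetric_two_indicator_closed_form(self):
        got = conditional_loglik([1.0, 0.0], [1.0, -1.0], "logit")
        assert got == pytest.approx(-2.0 * np.log(1.0 + np.exp(-1.0)))


class TestMarginalLoglik:
    def test_zero_loadings_decompose_into_glms(self, moderate_spec, moderate_data):
        """With no latent attachment the marginal LL is a sum of independent
        Bernoulli regressions evaluated at the same intercepts."""
        import statsmodels.api as sm

        zero = ModelSpec(
            latents=moderate_spec.latents,
            indicators=tuple(
                Indicator(i.name, i.latent, i.link, 0.0, i.direct_covariates)
                for i in moderate_spec.indicators
            ),
            covariates=moderate_spec.covariates,
            latent_paths=moderate_spec.latent_paths,
            covariate_to_latent_paths=moderate_spec.covariate_to_latent_paths,
        )
        layout = mg.param_layout(zero)
        vals = {f"intercept:{n}": c for n, c in
                [("stunting", -0.2), ("wasting", 0.4), ("underweight", -0.6),
                 ("diarrhea", 0.1), ("cough", -1.0), ("fever", 0.8)]}
        theta = ParameterVector.from_dict(layout, vals)
        ll = marginal_loglik(theta, moderate_data, zero, q=7, adaptive=True)
        oracle = 0.0
        for name in zero.indicator_names():
            y = moderate_data[name].to_numpy()
            z = np.full_like(y, vals[f"intercept:{name}"])
            oracle += float(
                sm.families.Binomial().loglike_obs(y, 1 / (1 + np.exp(-z))).sum()
            )
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_probit_attenuation_identity(self, one_latent_spec):
        """One latent, probit: P(y=1) = Phi(a / sqrt(1 + lam^2 sigma^2))."""
        layout = mg.param_layout(one_latent_spec)
        vals = {"intercept:y1": -0.4, "intercept:y2": 0.3, "intercept:y3": -1.1,
                "loading:y2": 0.7, "loading:y3": 1.4, "lnsd:trait": np.log(0.9)}
        theta = ParameterVector.from_dict(layout, vals)
        spec = one_latent_spec.with_link("probit")
        # single-indicator rows isolate each marginal probability
        lam = {"y1": 1.0, "y2": 0.7, "y3": 1.4}
        sigma = 0.9
        rows, oracle = [], 0.0
        for name in ("y1", "y2", "y3"):
            row = {"y1": np.nan, "y2": np.nan, "y3": np.nan}
            row[name] = 1.0
            rows.append(row)
            pj = norm.cdf(vals[f"intercept:{name}"] /
                          np.sqrt(1 + lam[name] ** 2 * sigma ** 2))
            oracle += np.log(pj)
        data = pd.DataFrame(rows)
        ll = marginal_loglik(theta, data, spec, q=15, adaptive=True, missing="use")
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_matches_dense_trapezoid_r2(self, moderate_spec, moderate_theta, moderate_data):
        """Brute-force oracle: 2-D trapezoid integration on [-8,8]^2."""
        tv = moderate_theta.values
        ll = marginal_loglik(tv, moderate_data, moderate_spec, q=15, adaptive=True)
        oracle = _trapezoid_loglik(moderate_spec, moderate_theta, moderate_data)
        assert ll == pytest.approx(oracle, rel=1e-5)

    def test_row_and_indicator_order_invariance(self, moderate_spec, moderate_theta,
                                                moderate_data):
        tv = moderate_theta.values
        base = marginal_loglik(tv, moderate_data, moderate_spec, q=5)
        shuffled = moderate_data.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert marginal_loglik(tv, shuffled, moderate_spec, q=5) == pytest.approx(base, abs=1e-9)

        perm = [3, 4, 5, 0, 1, 2]
        spec2 = ModelSpec(
            latents=moderate_spec.latents,
            indicators=tuple(moderate_spec.indicators[j] for j in perm),
            covariates=moderate_spec.covariates,
            latent_paths=moderate_spec.latent_paths,
            covariate_to_latent_paths=moderate_spec.covariate_to_latent_paths,
        )
        theta2 = ParameterVector.from_dict(
            mg.param_layout(spec2),
            dict(zip(moderate_theta.layout.names, moderate_theta.values)),
        )
        assert marginal_loglik(theta2, moderate_data, spec2, q=5) == pytest.approx(base, abs=1e-9)

    @pytest.mark.parametrize("link", ["logit", "probit", "cloglog"])
    def test_finite_on_all_zero_and_all_one_rows(self, moderate_spec, moderate_theta, link):
        inds = list(moderate_spec.indicator_names())
        data = pd.DataFrame([{**{k: 0.0 for k in inds}, "wealth_index": "poor",
                              "breastfeeding": "no"},
                             {**{k: 1.0 for k in inds}, "wealth_index": "rich",
                              "breastfeeding": "yes"}])
        ll = marginal_loglik(moderate_theta.values, data, moderate_spec.with_link(link), q=7)
        assert np.isfinite(ll)

    def test_adaptive_matches_dense_nonadaptive(self, moderate_spec, moderate_theta,
                                                moderate_data):
        """Adaptive q=7 within 1e-4 of plain q=40 in total LL (n=200, r=2)."""
        tv = moderate_theta.values
        ll_ad = marginal_loglik(tv, moderate_data, moderate_spec, q=7, adaptive=True)
        ll_pl = marginal_loglik(tv, moderate_data, moderate_spec, q=40, adaptive=False)
        assert ll_ad == pytest.approx(ll_pl, abs=1e-4)

    def test_analytic_gradient_matches_finite_differences(self, moderate_spec,
                                                          moderate_theta, moderate_data):
        ev = MarginalLikelihood(moderate_spec, moderate_data, q=5, adaptive=True)
        tv = moderate_theta.values
        ev.adapt(tv)
        _, g = ev.loglik_grad(tv)
        rng = np.random.default_rng(1)
        for i in rng.choice(len(g), size=8, replace=False):
            h = 1e-6 * (1 + abs(tv[i]))
            tp, tm = tv.copy(), tv.copy()
            tp[i] += h
            tm[i] -= h
            fd = (ev.loglik(tp, refresh=False) - ev.loglik(tm, refresh=False)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=5e-6, abs=1e-6)


def _trapezoid_loglik(spec, theta, data, lim=8.0, npts=400):
    """Dense 2-D trapezoid integration oracle for the marginal likelihood."""
    grid = np.linspace(-lim, lim, npts)
    V1, V2 = np.meshgrid(grid, grid, indexing="ij")
    nodes = np.column_stack([V1.ravel(), V2.ravel()])
    log_phi = norm.logpdf(nodes).sum(axis=1)
    total = 0.0
    dx = grid[1] - grid[0]
    for _, row in data.iterrows():
        x = {c.name: row[c.name] for c in spec.covariates}
        y = row[list(spec.indicator_names())].to_numpy(dtype=float)
        ll_nodes = np.empty(len(nodes))
        # affine in v: evaluate z at three basis points and extend linearly
        z0 = linear_predictor(theta, x, np.zeros(2), spec).z
        z1 = linear_predictor(theta, x, np.array([1.0, 0.0]), spec).z - z0
        z2 = linear_predictor(theta, x, np.array([0.0, 1.0]), spec).z - z0
        Z = z0[None, :] + nodes[:, :1] * z1[None, :] + nodes[:, 1:] * z2[None, :]
        P = 1 / (1 + np.exp(-Z))
        mask = ~np.isnan(y)
        ll_nodes = (y[mask] * np.log(P[:, mask])
                    + (1 - y[mask]) * np.log(1 - P[:, mask])).sum(axis=1)
        integrand = np.exp(ll_nodes + log_phi).reshape(npts, npts)
        total += np.log(np.trapezoid(np.trapezoid(integrand, dx=dx), dx=dx))
    return total
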