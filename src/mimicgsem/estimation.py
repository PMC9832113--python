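"""Maximum-likelihood estimation of the generalized SEM.

The marginal likelihood is maximized by L-BFGS-B with exact analytic
gradients of the quadrature objective. Under adaptive quadrature the
per-child grid centres depend on theta, so estimation alternates: freeze the
grid at the current theta, maximize the frozen-grid objective, re-adapt, and
repeat until the re-adapted log-likelihood stabilizes. Standard errors come
from the numerically differentiated observed information (central differences
of the analytic gradient) at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.optimize as spo
from scipy.special import ndtri
from scipy.stats import norm
import statsmodels.api as sm

from .likelihood import MarginalLikelihood, ParameterVector, _as_values
from .model_spec import ModelSpec, param_layout, structural_problems, validate_spec

LINK_ORDER = ("logit", "probit", "cloglog")

_SM_LINKS = {
    "logit": sm.families.links.Logit,
    "probit": sm.families.links.Probit,
    "cloglog": sm.families.links.CLogLog,
}


def _link_of_prob(link: str, p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    if link == "logit":
        return float(np.log(p / (1 - p)))
    if link == "probit":
        return float(ndtri(p))
    if link == "cloglog":
        return float(np.log(-np.log1p(-p)))
    raise ValueError(f"unknown link {link!r}")


def starting_values(spec: ModelSpec, data: pd.DataFrame, link: str = "logit",
                    missing: str = "drop") -> ParameterVector:
    """Initial parameters: per-indicator binary GLMs for intercepts and
    direct effects, free loadings at 1, latent regressions at 0, L at identity.
    """
    ev = MarginalLikelihood(spec, data, link=link, q=1, adaptive=False, missing=missing)
    st = ev.struct
    theta = ParameterVector(ev.layout)
    for j, idx in st.free_loading:
        theta[idx] = 1.0
    for j, ind in enumerate(spec.indicators):
        obs = ev.design.mask[:, j]
        y = ev.design.Y[obs, j]
        X = ev.design.Xdir[j][obs]
        prev = float(y.mean()) if y.size else 0.5
        fallback_int = _link_of_prob(ind.link, prev)
        if X.shape[1] == 0 or y.size == 0:
            theta[f"intercept:{ind.name}"] = fallback_int
            continue
        Xc = np.column_stack([np.ones(y.size), X])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fam = sm.families.Binomial(link=_SM_LINKS[ind.link]())
                res = sm.GLM(y, Xc, family=fam).fit(maxiter=100)
            coefs = np.asarray(res.params)
            if not np.all(np.isfinite(coefs)) or np.max(np.abs(coefs)) > 15:
                raise ValueError("separation-like starting regression")
        except Exception:
            warnings.warn(
                f"starting regression for {ind.name!r} failed; using zero coefficients",
                RuntimeWarning,
            )
            coefs = np.zeros(Xc.shape[1])
            coefs[0] = fallback_int
        theta[f"intercept:{ind.name}"] = coefs[0]
        if st.i_gamma[j].size:
            theta.values[st.i_gamma[j]] = coefs[1:]
    return theta


@dataclass
class FitResult:
    """Estimates and diagnostics from one maximum-likelihood fit."""

    params: ParameterVector
    spec: ModelSpec
    link: str
    loglik: float
    n: int
    p: int
    converged: bool
    iterations: int
    q: int
    adaptive: bool
    missing: str
    grad_norm: float
    free: np.ndarray
    fixed: dict = field(default_factory=dict)
    warnings_: list = field(default_factory=list)
    se: Optional[pd.Series] = None
    vcov: Optional[np.ndarray] = None
    _evaluator: Optional[MarginalLikelihood] = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.p

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.p * np.log(self.n)

    def estimates(self) -> pd.Series:
        return self.params.to_series()

    def wald_table(self) -> pd.DataFrame:
        """Estimates, SEs, 95% Wald CIs, AORs and significance stars."""
        if self.se is None:
            raise ValueError("run standard_errors(fit) first")
        est = self.estimates()
        se = self.se
        lo, hi = est - 1.96 * se, est + 1.96 * se
        zval = est / se
        pval = 2.0 * norm.sf(np.abs(zval))
        stars = pd.Series(
            np.where(pval < 0.001, "**", np.where(pval < 0.05, "*", "")), index=est.index
        )
        return pd.DataFrame(
            {
                "estimate": est, "se": se, "ci_lo": lo, "ci_hi": hi,
                "aor": np.exp(est), "aor_lo": np.exp(lo), "aor_hi": np.exp(hi),
                "p_value": pval, "stars": stars,
            }
        )

    def to_dict(self) -> dict:
        return {
            "link": self.link,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n": self.n,
            "p": self.p,
            "q": self.q,
            "adaptive": self.adaptive,
            "missing": self.missing,
            "converged": bool(self.converged),
            "iterations": self.iterations,
            "grad_norm": self.grad_norm,
            "estimates": dict(zip(self.params.layout.names, self.params.values.tolist())),
            "se": None if self.se is None else {
                k: (None if not np.isfinite(v) else float(v)) for k, v in self.se.items()
            },
            "vcov": None if self.vcov is None else self.vcov.tolist(),
            "fixed": self.fixed,
            "spec": self.spec.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        spec = ModelSpec.from_dict(d["spec"])
        layout = param_layout(spec)
        params = ParameterVector.from_dict(layout, d["estimates"])
        free = np.ones(len(layout), dtype=bool)
        for name in d.get("fixed", {}):
            free[layout.index(name)] = False
        fr = cls(
            params=params, spec=spec, link=d["link"], loglik=d["loglik"], n=d["n"],
            p=d["p"], converged=d["converged"], iterations=d["iterations"], q=d["q"],
            adaptive=d["adaptive"], missing=d.get("missing", "drop"),
            grad_norm=d.get("grad_norm", np.nan), free=free, fixed=d.get("fixed", {}),
        )
        if d.get("se") is not None:
            fr.se = pd.Series(
                {k: (np.nan if v is None else v) for k, v in d["se"].items()}
            ).reindex(list(layout.names))
        if d.get("vcov") is not None:
            fr.vcov = np.asarray(d["vcov"], dtype=float)
        return fr


def fit(spec: ModelSpec, data: pd.DataFrame, link: str = "logit", q: int = 7,
        adaptive: bool = True, seed: int = 0, start: Optional[ParameterVector] = None,
        fix: Optional[dict] = None, missing: str = "drop", maxiter: int = 500,
        inner_maxiter: int = 60, max_outer: int = 50, outer_tol: float = 1e-8) -> FitResult:
    """Maximize the marginal likelihood. Deterministic given data and options.

    Adaptive estimation alternates short L-BFGS-B runs on the frozen-grid
    objective (at most ``inner_maxiter`` iterations each, ``maxiter`` in
    total) with grid re-adaptation, and uses the *re-adapted* log-likelihood
    as the merit function: a round that lowers it is retried from the previous
    iterate with a smaller inner budget. This guards against the optimizer
    exploiting quadrature error of a stale grid at small q. Convergence is a
    relative re-adapted-LL change below ``outer_tol`` across a round.

    ``fix`` maps parameter names to values held constant during estimation
    (e.g. pinning the structural path at 0 for a nested comparison). ``seed``
    is accepted for interface symmetry with the stochastic operations; the
    optimizer itself is deterministic.
    """
    report = validate_spec(spec)
    bad = structural_problems(report)
    if bad:
        raise ValueError("invalid model spec: " + "; ".join(bad))
    ev = MarginalLikelihood(spec, data, link=link, q=q, adaptive=adaptive, missing=missing)
    layout = ev.layout
    theta = (start.copy() if start is not None
             else starting_values(ev.spec, data, link=link, missing=missing))
    if theta.layout.names != layout.names:
        raise ValueError("starting values use a different parameter layout")
    free = np.ones(len(layout), dtype=bool)
    fix = dict(fix or {})
    for name, value in fix.items():
        i = layout.index(name)
        free[i] = False
        theta[i] = value
    full = theta.values.copy()

    def unpack(x):
        th = full.copy()
        th[free] = x
        return th

    def negobj(x):
        ll, g = ev.loglik_grad(unpack(x))
        return -ll, -g[free]

    # generous box bounds keep ill-fitting links (notably cloglog on
    # logit-generated tails) from running away to clipped regions
    bounds = []
    for name, is_free in zip(layout.names, free):
        if not is_free:
            continue
        if name.startswith("lnsd:"):
            bounds.append((-4.0, 4.0))
        else:
            bounds.append((-25.0, 25.0))

    def lbfgs(x0, cap):
        return spo.minimize(
            negobj, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": cap, "ftol": 1e-13, "gtol": 5e-6, "maxcor": 25},
        )

    x = full[free].copy()
    iterations = 0
    converged = False
    if not adaptive:
        res = lbfgs(x, maxiter)
        x = res.x
        iterations = int(res.nit)
        converged = bool(res.success)
        ll_prev = ev.loglik(unpack(x), refresh=False)
    else:
        ll_prev = ev.loglik(unpack(x), refresh=True)
        budget = maxiter
        for _ in range(max_outer):
            if budget <= 0:
                break
            ev.adapt(unpack(x))
            cap = min(inner_maxiter, budget)
            # small re-adapted-LL decreases are expected on the way to the
            # adaptive fixed point (the quadrature error moves with theta);
            # only collapse beyond this margin marks a stale-grid overshoot
            drop_tol = max(0.5, 1e-4 * max(1.0, abs(ll_prev)))
            while True:
                res = lbfgs(x, cap)
                ll_new = ev.loglik(unpack(res.x), refresh=True)
                if ll_new >= ll_prev - drop_tol or cap <= 2:
                    break
                cap = max(cap // 4, 2)  # overshoot: retry with a shorter leash
            iterations += int(res.nit)
            budget -= int(res.nit)
            accepted = ll_new >= ll_prev - drop_tol
            if accepted:
                x = res.x
            else:
                break  # diverging even with tiny steps; stop at the last good iterate
            inner_done = res.status == 0  # not cut off by the per-round cap
            if inner_done and abs(ll_new - ll_prev) <= outer_tol * max(1.0, abs(ll_new)):
                converged = True
                ll_prev = ll_new
                break
            ll_prev = ll_new
    theta_hat = ParameterVector(layout, unpack(x))
    _, g = ev.loglik_grad(theta_hat.values)
    scale = np.maximum(1.0, np.abs(theta_hat.values[free]))
    grad_norm = float(np.max(np.abs(g[free] / scale))) if free.any() else 0.0
    result = FitResult(
        params=theta_hat, spec=ev.spec, link=link or "mixed", loglik=float(ll_prev),
        n=ev.n, p=int(free.sum()), converged=converged, iterations=iterations,
        q=q, adaptive=adaptive, missing=missing, grad_norm=grad_norm,
        free=free, fixed=fix, warnings_=list(report.problems),
        _evaluator=ev,
    )
    if not converged:
        warnings.warn(
            f"fit did not converge (grad_norm={grad_norm:.2e}); returning partial result",
            RuntimeWarning,
        )
    return result


def standard_errors(fit_result: FitResult, data: Optional[pd.DataFrame] = None,
                    spec: Optional[ModelSpec] = None, step: float = 1e-5) -> pd.Series:
    """SEs from the inverse numerically differentiated observed information.

    The Hessian of the (frozen-grid) log-likelihood at theta-hat is formed by
    central differences of the analytic gradient. Parameters fixed by
    identification get no SE (NaN) and zero rows in the stored covariance, so
    downstream delta-method propagation treats them as known constants.
    """
    ev = fit_result._evaluator
    if ev is None:
        if data is None:
            raise ValueError("provide the original data to rebuild the likelihood")
        ev = MarginalLikelihood(
            spec or fit_result.spec, data, link=fit_result.link,
            q=fit_result.q, adaptive=fit_result.adaptive, missing=fit_result.missing,
        )
    theta = fit_result.params.values.copy()
    ev.adapt(theta)
    free = fit_result.free
    idx = np.flatnonzero(free)
    k = idx.size
    H = np.zeros((k, k))
    for a, i in enumerate(idx):
        h = step * (1.0 + abs(theta[i]))
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        _, gp = ev.loglik_grad(tp)
        _, gm = ev.loglik_grad(tm)
        H[a] = (gp[idx] - gm[idx]) / (2.0 * h)
    H = 0.5 * (H + H.T)
    info = -H
    vcov_free = None
    try:
        vcov_free = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov_free = np.linalg.pinv(info)
    diag = np.diag(vcov_free).copy()
    diag[diag <= 0] = np.nan
    se_free = np.sqrt(diag)
    se = np.full(len(theta), np.nan)
    se[idx] = se_free
    vcov = np.zeros((len(theta), len(theta)))
    vcov[np.ix_(idx, idx)] = vcov_free
    fit_result.se = pd.Series(se, index=list(fit_result.params.layout.names))
    fit_result.vcov = vcov
    return fit_result.se


@dataclass
class LinkComparison:
    """AIC/BIC comparison of the three link families on identical data."""

    table: pd.DataFrame  # rows in fixed order logit, probit, cloglog
    selected: str
    fits: dict

    def __repr__(self):
        return f"LinkComparison(selected={self.selected!r})\n{self.table}"


def compare_links(spec: ModelSpec, data: pd.DataFrame, q: int = 7,
                  adaptive: bool = True, **fit_kwargs) -> LinkComparison:
    """Fit logit, probit and cloglog and select the AIC-minimal link.

    Ties break toward logit (the row order). A link whose fit raises is kept
    as a failed row and excluded from selection.
    """
    rows = []
    fits = {}
    for link in LINK_ORDER:
        try:
            fr = fit(spec, data, link=link, q=q, adaptive=adaptive, **fit_kwargs)
            fits[link] = fr
            rows.append(
                {"link": link, "loglik": fr.loglik, "aic": fr.aic, "bic": fr.bic,
                 "p": fr.p, "converged": fr.converged, "failed": False}
            )
        except Exception as exc:  # pragma: no cover - defensive path
            warnings.warn(f"{link} fit failed: {exc}", RuntimeWarning)
            rows.append(
                {"link": link, "loglik": np.nan, "aic": np.nan, "bic": np.nan,
                 "p": np.nan, "converged": False, "failed": True}
            )
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    if ok.empty:
        raise RuntimeError("all link fits failed")
    best_aic = ok["aic"].min()
    selected = ok.loc[ok["aic"] <= best_aic, "link"].iloc[0]
    return LinkComparison(table=table, selected=str(selected), fits=fits)
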