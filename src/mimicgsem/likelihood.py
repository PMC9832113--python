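"""Marginal likelihood of the generalized SEM by (adaptive) Gauss-Hermite
quadrature.

Writing v for the r-vector of independent standard-normal latent
disturbances, the latent traits solve eta = B_eta eta + B_x x + L v, i.e.
eta = T (B_x x + L v) with T = (I - B_eta)^{-1}, and each indicator j has
linear predictor z_j = intercept_j + lambda_j * eta_parent(j) + gamma_j' x.
Conditional on v the indicators are independent Bernoulli through their link,
so the child-level marginal likelihood is the r-dimensional integral of
exp(sum_j loglik_j(z_j(v))) against phi_r(v), approximated on a (possibly
per-child adapted) product quadrature grid with log-sum-exp stabilization.

The evaluator exposes exact analytic gradients of the quadrature objective
for a *frozen* set of nodes/weights; estimation re-adapts the nodes between
optimizer rounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, log_ndtr, logsumexp, ndtr

from .model_spec import ModelSpec, ParameterLayout, param_layout
from .quadrature import AdaptiveState, ghq_rule, product_grid

_LOG2PI = float(np.log(2.0 * np.pi))
_PCLIP = 1e-12


# ---------------------------------------------------------------------------
# link numerics


def inverse_link(link: str, z) -> np.ndarray:
    """Map a linear predictor to a probability in (0,1), clamped at 1e-12."""
    z = np.asarray(z, dtype=float)
    if link == "logit":
        p = expit(z)
    elif link == "probit":
        p = ndtr(z)
    elif link == "cloglog":
        p = -np.expm1(-np.exp(np.clip(z, -700.0, 30.0)))
    else:
        raise ValueError(f"unknown link {link!r}")
    return np.clip(p, _PCLIP, 1.0 - _PCLIP)


def _norm_logpdf(z):
    return -0.5 * (z * z + _LOG2PI)


def _bernoulli_loglik(link: str, y, z):
    """Elementwise log f(y | z); stable in the tails."""
    if link == "logit":
        return y * z - np.logaddexp(0.0, z)
    if link == "probit":
        return y * log_ndtr(z) + (1.0 - y) * log_ndtr(-z)
    if link == "cloglog":
        u = np.exp(np.clip(z, -700.0, 30.0))
        p = np.maximum(-np.expm1(-u), 1e-300)
        return y * np.log(p) - (1.0 - y) * u
    raise ValueError(f"unknown link {link!r}")


def _bernoulli_score_hess(link: str, y, z):
    """First and second derivatives of log f(y|z) with respect to z.

    All three links have concave log-likelihoods in z (the logistic, normal
    and Gumbel densities are log-concave), so the second derivative is <= 0.
    """
    if link == "logit":
        p = expit(z)
        return y - p, -p * (1.0 - p)
    if link == "probit":
        lam1 = np.exp(_norm_logpdf(z) - log_ndtr(z))
        lam0 = np.exp(_norm_logpdf(z) - log_ndtr(-z))
        s = y * lam1 - (1.0 - y) * lam0
        h = y * (-lam1 * (lam1 + z)) + (1.0 - y) * (-lam0 * (lam0 - z))
        return s, h
    if link == "cloglog":
        u = np.exp(np.clip(z, -700.0, 30.0))
        p = np.maximum(-np.expm1(-u), 1e-300)
        s1 = u * np.exp(-u) / p
        s = y * s1 - (1.0 - y) * u
        h = y * (s1 * (1.0 - u) - s1 * s1) - (1.0 - y) * u
        return s, h
    raise ValueError(f"unknown link {link!r}")


# ---------------------------------------------------------------------------
# parameter vector


class ParameterVector:
    """A flat parameter vector with named access through a ParameterLayout."""

    def __init__(self, layout: ParameterLayout, values=None):
        self.layout = layout
        if values is None:
            values = np.zeros(len(layout))
        values = np.asarray(values, dtype=float).copy()
        if values.shape != (len(layout),):
            raise ValueError(
                f"parameter vector has length {values.size}, layout expects {len(layout)}"
            )
        self.values = values

    @classmethod
    def from_dict(cls, layout: ParameterLayout, d: dict, default: float = 0.0):
        pv = cls(layout, np.full(len(layout), default))
        for k, v in d.items():
            pv[k] = v
        return pv

    def __len__(self):
        return len(self.values)

    def _idx(self, key):
        return self.layout.index(key) if isinstance(key, str) else key

    def __getitem__(self, key):
        return self.values[self._idx(key)]

    def __setitem__(self, key, value):
        self.values[self._idx(key)] = value

    def copy(self) -> "ParameterVector":
        return ParameterVector(self.layout, self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.layout.names))

    def __repr__(self):
        return f"ParameterVector({len(self)} parameters)"


# ---------------------------------------------------------------------------
# structure: layout index maps + theta unpacking


class _Structure:
    """Precomputed index maps between the flat vector and model blocks."""

    def __init__(self, spec: ModelSpec, layout: Optional[ParameterLayout] = None):
        self.spec = spec
        self.layout = layout or param_layout(spec)
        names = list(self.layout.names)
        pos = {n: i for i, n in enumerate(names)}
        inds = spec.indicators
        lats = spec.latent_names()
        self.J = len(inds)
        self.r = len(lats)
        self.lat_index = {n: k for k, n in enumerate(lats)}
        self.parent = np.array([self.lat_index[i.latent] for i in inds])
        self.links = tuple(i.link for i in inds)

        self.i_intercept = np.array([pos[f"intercept:{i.name}"] for i in inds])
        self.free_loading = [
            (j, pos[f"loading:{i.name}"]) for j, i in enumerate(inds) if i.fixed_loading is None
        ]
        self.lam_base = np.array(
            [i.fixed_loading if i.fixed_loading is not None else 0.0 for i in inds]
        )
        self.i_gamma = []  # per indicator: index array into theta
        self.direct_cols = []  # per indicator: design column names
        for i in inds:
            cols = [c for cv in i.direct_covariates for c in spec.covariate(cv).design_columns()]
            self.direct_cols.append(cols)
            self.i_gamma.append(np.array([pos[f"direct:{i.name}:{c}"] for c in cols], dtype=int))
        self.i_b = []  # per latent
        self.latent_cols = []
        for l in lats:
            cols = [
                c for cv in spec.covariates_into(l) for c in spec.covariate(cv).design_columns()
            ]
            self.latent_cols.append(cols)
            self.i_b.append(np.array([pos[f"reg:{l}<-{c}"] for c in cols], dtype=int))
        self.struct_entries = [
            (self.lat_index[to], self.lat_index[frm], pos[f"struct:{to}<-{frm}"])
            for (frm, to) in sorted(
                set(spec.latent_paths), key=lambda p: (self.lat_index[p[1]], self.lat_index[p[0]])
            )
        ]
        self.i_lnsd = np.array([pos[f"lnsd:{l}"] for l in lats])
        self.lchol_entries = []
        if spec.full_covariance:
            for row in range(1, self.r):
                for col in range(row):
                    self.lchol_entries.append(
                        (row, col, pos[f"lchol:{lats[row]}:{lats[col]}"])
                    )

    def unpack(self, theta: np.ndarray):
        a = theta[self.i_intercept]
        lam = self.lam_base.copy()
        for j, idx in self.free_loading:
            lam[j] = theta[idx]
        gammas = [theta[ix] for ix in self.i_gamma]
        bs = [theta[ix] for ix in self.i_b]
        Beta = np.zeros((self.r, self.r))
        for t, f, idx in self.struct_entries:
            Beta[t, f] = theta[idx]
        L = np.diag(np.exp(theta[self.i_lnsd]))
        for row, col, idx in self.lchol_entries:
            L[row, col] = theta[idx]
        T = np.linalg.inv(np.eye(self.r) - Beta)
        return a, lam, gammas, bs, Beta, L, T


class _Design:
    """Numeric design arrays for one dataset under one spec."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, missing: str = "drop",
                 require_outcomes: bool = True):
        if missing not in ("drop", "use"):
            raise ValueError("missing must be 'drop' or 'use'")
        struct = _Structure(spec)
        ind_names = list(spec.indicator_names())
        need_covs = sorted(
            {cv for i in spec.indicators for cv in i.direct_covariates}
            | {c for (c, _l) in spec.covariate_to_latent_paths}
        )
        required = (ind_names if require_outcomes else []) + need_covs
        missing_cols = [c for c in required if c not in data.columns]
        if missing_cols:
            raise ValueError(f"dataset lacks required columns: {missing_cols}")

        present = [c for c in ind_names if c in data.columns]
        Y = np.full((len(data), len(ind_names)), np.nan)
        if present:
            sub = data[present].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
            for k, c in enumerate(present):
                Y[:, ind_names.index(c)] = sub[:, k]
        bad = np.zeros_like(Y, dtype=bool)
        if present:
            raw_na = data[present].isna().to_numpy()
            cols = [ind_names.index(c) for c in present]
            # a value that fails numeric coercion (NaN now, not NaN in the raw
            # frame) or is numeric but not 0/1 is invalid
            bad[:, cols] = (np.isnan(Y[:, cols]) & ~raw_na) | (
                ~np.isnan(Y[:, cols]) & (Y[:, cols] != 0.0) & (Y[:, cols] != 1.0)
            )
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"indicator {ind_names[j]!r} has non-binary value at row {i}"
            )
        keep = np.ones(len(data), dtype=bool)
        if need_covs:
            keep &= data[need_covs].notna().all(axis=1).to_numpy()
        if require_outcomes:
            if missing == "drop":
                keep &= ~np.isnan(Y).any(axis=1)
            else:
                keep &= ~np.isnan(Y).all(axis=1)
        self.index = np.flatnonzero(keep)
        data = data.iloc[self.index]
        Y = Y[keep]
        self.mask = ~np.isnan(Y)
        self.Y = np.nan_to_num(Y)
        self.n = Y.shape[0]
        if self.n == 0:
            raise ValueError("no usable rows after missing-data handling")

        def dummies(cols):
            if not cols:
                return np.zeros((self.n, 0))
            mats = []
            for col in cols:
                cov, level = col.split("=", 1)
                vals = data[cov].astype(str)
                levels = set(map(str, spec.covariate(cov).levels))
                unknown = ~vals.isin(levels)
                if unknown.any():
                    first = vals[unknown].iloc[0]
                    raise ValueError(
                        f"covariate {cov!r} has undeclared level {first!r}"
                    )
                mats.append((vals == level).to_numpy(dtype=float))
            return np.stack(mats, axis=1)

        self.Xdir = [dummies(cols) for cols in struct.direct_cols]
        self.Xlat = [dummies(cols) for cols in struct.latent_cols]
        self.struct = struct


# ---------------------------------------------------------------------------
# small public helpers


@dataclass(frozen=True)
class LinearPredictor:
    """Per-indicator linear predictors z and latent values eta at a given v."""

    z: np.ndarray  # (J,)
    eta: np.ndarray  # (r,)
    indicator_names: tuple


def _one_row_frame(spec: ModelSpec, x) -> pd.DataFrame:
    row = dict(x)
    for name in spec.indicator_names():
        row.setdefault(name, np.nan)
    return pd.DataFrame([row])


def linear_predictor(theta, x, v, spec: ModelSpec) -> LinearPredictor:
    """Evaluate z_j(v) for one observation; affine in v for fixed theta.

    ``x`` maps covariate names to level values (indicator entries optional);
    ``v`` is the r-vector of standard-normal disturbances.
    """
    theta = _as_values(theta, spec)
    design = _Design(spec, _one_row_frame(spec, x), missing="use", require_outcomes=False)
    st = design.struct
    v = np.asarray(v, dtype=float)
    if v.shape != (st.r,):
        raise ValueError(f"v must have dimension {st.r}")
    a, lam, gammas, bs, _Beta, L, T = st.unpack(theta)
    c0 = np.array([design.Xlat[t][0] @ bs[t] for t in range(st.r)])
    eta = T @ (c0 + L @ v)
    z = a.copy()
    for j in range(st.J):
        z[j] += lam[j] * eta[st.parent[j]] + design.Xdir[j][0] @ gammas[j]
    return LinearPredictor(z=z, eta=eta, indicator_names=spec.indicator_names())


def conditional_loglik(y, z, link) -> float:
    """Sum of Bernoulli log-likelihoods over non-missing indicators.

    ``link`` may be one name or a sequence of per-indicator names.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    links = [link] * y.size if isinstance(link, str) else list(link)
    total = 0.0
    for j in range(y.size):
        if not np.isnan(y[j]):
            total += float(_bernoulli_loglik(links[j], y[j], z[j]))
    return total


def _as_values(theta, spec: ModelSpec) -> np.ndarray:
    if isinstance(theta, ParameterVector):
        return theta.values
    return np.asarray(theta, dtype=float)


# ---------------------------------------------------------------------------
# the evaluator


class MarginalLikelihood:
    """Quadrature marginal log-likelihood for one (spec, dataset, options).

    With ``adaptive=True`` the grid is recentred per child at the posterior
    mode/curvature of v whenever :meth:`adapt` is called; :meth:`loglik` and
    :meth:`loglik_grad` evaluate (and differentiate exactly) the objective on
    the currently frozen grid. ``loglik(theta, refresh=True)`` re-adapts first,
    giving the fully adaptive approximation at theta.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, link: Optional[str] = None,
                 q: int = 7, adaptive: bool = True, missing: str = "drop",
                 require_outcomes: bool = True):
        if link is not None:
            spec = spec.with_link(link)
        self.spec = spec
        self.q = int(q)
        self.adaptive = bool(adaptive)
        self.design = _Design(spec, data, missing=missing, require_outcomes=require_outcomes)
        self.struct = self.design.struct
        self.layout = self.struct.layout
        grid = product_grid(ghq_rule(self.q), self.struct.r)
        self._base_nodes = grid.nodes  # (K, r)
        self._base_logw = np.log(grid.weights)
        self._nodes = self._base_nodes  # (K,r) shared or (n,K,r) adapted
        self._logw = self._base_logw  # (K,) or (n,K)

    @property
    def n(self) -> int:
        return self.design.n

    @property
    def n_params(self) -> int:
        return len(self.layout)

    # -- core pieces -------------------------------------------------------
    def _predictor_parts(self, theta):
        st = self.struct
        a, lam, gammas, bs, _Beta, L, T = st.unpack(theta)
        c0 = np.zeros((self.n, st.r))
        for t in range(st.r):
            if self.design.Xlat[t].shape[1]:
                c0[:, t] = self.design.Xlat[t] @ bs[t]
        Tc = c0 @ T.T
        zbase = np.tile(a, (self.n, 1))
        for j in range(st.J):
            if self.design.Xdir[j].shape[1]:
                zbase[:, j] += self.design.Xdir[j] @ gammas[j]
        M = T @ L
        return a, lam, gammas, Tc, zbase, M, L, T

    def _eta_z(self, theta):
        st = self.struct
        a, lam, gammas, Tc, zbase, M, L, T = self._predictor_parts(theta)
        V = self._nodes
        VM = V @ M.T  # (K,r) or (n,K,r)
        if VM.ndim == 2:
            eta = Tc[:, None, :] + VM[None, :, :]
        else:
            eta = Tc[:, None, :] + VM
        etapar = eta[:, :, st.parent]
        z = zbase[:, None, :] + lam[None, None, :] * etapar
        return lam, eta, etapar, z, L, T

    def _masked_ll(self, z):
        st = self.struct
        Y = self.design.Y[:, None, :]
        ll = np.empty_like(z)
        for link in set(st.links):
            cols = [j for j, lk in enumerate(st.links) if lk == link]
            ll[:, :, cols] = _bernoulli_loglik(link, Y[:, :, cols], z[:, :, cols])
        ll *= self.design.mask[:, None, :]
        return ll

    def _masked_score_hess(self, z):
        st = self.struct
        Y = self.design.Y[:, None, :]
        s = np.empty_like(z)
        h = np.empty_like(z)
        for link in set(st.links):
            cols = [j for j, lk in enumerate(st.links) if lk == link]
            sc, hc = _bernoulli_score_hess(link, Y[:, :, cols], z[:, :, cols])
            s[:, :, cols] = sc
            h[:, :, cols] = hc
        m = self.design.mask[:, None, :]
        s *= m
        h *= m
        return s, h

    # -- adaptation --------------------------------------------------------
    def posterior_modes(self, theta):
        """Batched posterior modes/curvatures of v given theta.

        Returns (mu (n,r), C (n,r,r) Cholesky of the curvature, logdetC (n,)).
        """
        theta = _as_values(theta, self.spec)
        st = self.struct
        a, lam, gammas, Tc, zbase, M, L, T = self._predictor_parts(theta)
        Jm = lam[:, None] * M[st.parent, :]  # (J, r)
        t0 = zbase + lam[None, :] * Tc[:, st.parent]
        Y, mask = self.design.Y, self.design.mask
        n, r = self.n, st.r
        v = np.zeros((n, r))
        eye = np.eye(r)

        def obj_score_hess(v, with_derivs=True):
            z = t0 + v @ Jm.T
            ll = np.empty_like(z)
            s = h = None
            for link in set(st.links):
                cols = [j for j, lk in enumerate(st.links) if lk == link]
                ll[:, cols] = _bernoulli_loglik(link, Y[:, cols], z[:, cols])
            obj = -0.5 * np.sum(v * v, axis=1) + np.sum(ll * mask, axis=1)
            if not with_derivs:
                return obj, None, None
            s = np.empty_like(z)
            h = np.empty_like(z)
            for link in set(st.links):
                cols = [j for j, lk in enumerate(st.links) if lk == link]
                sc, hc = _bernoulli_score_hess(link, Y[:, cols], z[:, cols])
                s[:, cols] = sc
                h[:, cols] = hc
            s *= mask
            h *= mask
            g = -v + s @ Jm
            H = np.einsum("nj,jt,js->nts", h, Jm, Jm) - eye[None, :, :]
            return obj, g, H

        obj, g, H = obj_score_hess(v)
        for _ in range(50):
            if np.max(np.abs(g)) < 1e-8:
                break
            step = np.linalg.solve(H, g[:, :, None])[:, :, 0]  # Newton: v - H^{-1} g
            vnew = v - step
            objnew, _, _ = obj_score_hess(vnew, with_derivs=False)
            worse = objnew < obj - 1e-12
            halvings = 0
            while worse.any() and halvings < 25:
                step = np.where(worse[:, None], 0.5 * step, step)
                vnew = v - step
                objnew, _, _ = obj_score_hess(vnew, with_derivs=False)
                worse = objnew < obj - 1e-12
                halvings += 1
            v = vnew
            obj, g, H = obj_score_hess(v)
        negH = -H  # identity + PSD by log-concavity => positive definite
        tau = np.linalg.inv(negH)
        tau = 0.5 * (tau + np.transpose(tau, (0, 2, 1)))
        try:
            C = np.linalg.cholesky(tau)
        except np.linalg.LinAlgError:
            # fall back to the unadapted rule for any non-PD observation
            C = np.empty_like(tau)
            for i in range(n):
                try:
                    C[i] = np.linalg.cholesky(tau[i])
                except np.linalg.LinAlgError:
                    v[i] = 0.0
                    C[i] = eye
        logdetC = np.sum(np.log(np.diagonal(C, axis1=1, axis2=2)), axis=1)
        return v, C, logdetC

    def adapt(self, theta) -> None:
        """Recentre the quadrature grid at theta's posterior modes."""
        if not self.adaptive:
            return
        mu, C, logdetC = self.posterior_modes(theta)
        A = self._base_nodes  # (K, r)
        alpha = mu[:, None, :] + np.einsum("nrs,ks->nkr", C, A)
        base_q = 0.5 * np.sum(A * A, axis=1)  # -log phi_r(a_k) up to const
        self._nodes = alpha
        self._logw = (
            self._base_logw[None, :]
            + logdetC[:, None]
            + base_q[None, :]
            - 0.5 * np.sum(alpha * alpha, axis=2)
        )

    def reset_rule(self) -> None:
        self._nodes = self._base_nodes
        self._logw = self._base_logw

    # -- objective ---------------------------------------------------------
    def _per_obs_loglik(self, theta):
        _lam, _eta, _etapar, z, _L, _T = self._eta_z(theta)
        ll = self._masked_ll(z)
        lsum = ll.sum(axis=2)
        logw = self._logw if self._logw.ndim == 2 else self._logw[None, :]
        return logsumexp(lsum + logw, axis=1)

    def loglik(self, theta, refresh: Optional[bool] = None) -> float:
        """Total marginal log-likelihood; re-adapts the grid by default."""
        theta = _as_values(theta, self.spec)
        if refresh is None:
            refresh = self.adaptive
        if refresh:
            self.adapt(theta)
        li = self._per_obs_loglik(theta)
        if not np.all(np.isfinite(li)):
            bad = int(np.argmin(np.isfinite(li)))
            raise FloatingPointError(
                f"non-finite marginal likelihood at observation {bad}"
            )
        return float(li.sum())

    def loglik_grad(self, theta):
        """(loglik, gradient) of the frozen-grid objective; gradient is exact."""
        theta = _as_values(theta, self.spec)
        st = self.struct
        lam, eta, etapar, z, L, T = self._eta_z(theta)
        ll = self._masked_ll(z)
        lsum = ll.sum(axis=2)
        logw = self._logw if self._logw.ndim == 2 else self._logw[None, :]
        logpost = lsum + logw
        li = logsumexp(logpost, axis=1)
        total = float(li.sum())
        ptil = np.exp(logpost - li[:, None])  # (n, K) posterior node weights

        s, _h = self._masked_score_hess(z)
        grad = np.zeros(len(self.layout))

        sbar = np.einsum("nk,nkj->nj", ptil, s)
        np.add.at(grad, st.i_intercept, sbar.sum(axis=0))
        for j, ix in enumerate(st.i_gamma):
            if ix.size:
                grad[ix] += self.design.Xdir[j].T @ sbar[:, j]
        if st.free_loading:
            gl = np.einsum("nk,nkj->j", ptil, s * etapar)
            for j, idx in st.free_loading:
                grad[idx] += gl[j]

        lamP = np.zeros((st.J, st.r))
        lamP[np.arange(st.J), st.parent] = lam
        slam = s @ lamP  # (n,K,r): per-latent weighted scores
        Q = slam @ T  # chain through eta = T(...)
        Qw = ptil[:, :, None] * Q
        Qbar = Qw.sum(axis=1)
        for t, ix in enumerate(st.i_b):
            if ix.size:
                grad[ix] += self.design.Xlat[t].T @ Qbar[:, t]
        if st.struct_entries:
            GB = np.einsum("nkt,nkf->tf", Qw, eta)
            for t, f, idx in st.struct_entries:
                grad[idx] += GB[t, f]
        V = self._nodes
        if V.ndim == 3:
            GL = np.einsum("nkt,nks->ts", Qw, V)
        else:
            GL = np.einsum("nkt,ks->ts", Qw, V)
        for t in range(st.r):
            grad[st.i_lnsd[t]] += GL[t, t] * L[t, t]
        for row, col, idx in st.lchol_entries:
            grad[idx] += GL[row, col]
        return total, grad


def marginal_loglik(theta, data: pd.DataFrame, spec: ModelSpec, q: int = 7,
                    adaptive: bool = True, link: Optional[str] = None,
                    missing: str = "drop") -> float:
    """Marginal log-likelihood of the dataset at theta (functional API)."""
    ev = MarginalLikelihood(spec, data, link=link, q=q, adaptive=adaptive, missing=missing)
    return ev.loglik(theta)


def _single_observation_mode(params, observation, spec: ModelSpec, link=None) -> AdaptiveState:
    """Posterior mode/curvature of v for one observation (see quadrature)."""
    if link is not None:
        spec = spec.with_link(link)
    frame = _one_row_frame(spec, observation)
    ev = MarginalLikelihood(spec, frame, q=1, adaptive=True, missing="use",
                            require_outcomes=False)
    theta = _as_values(params, spec)
    mu, C, _ = ev.posterior_modes(theta)
    tau = C[0] @ C[0].T
    return AdaptiveState(mode=mu[0], curvature=tau)
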