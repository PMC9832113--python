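"""Gauss-Hermite quadrature against the standard-normal weight, with
per-observation adaptive recentring.

The raw Gauss-Hermite rule integrates against exp(-x^2); rescaling the
abscissas by sqrt(2) and the weights by 1/sqrt(pi) turns it into a rule for
the standard-normal density, so the weights sum to one. Product grids extend
the rule to r latent dimensions. Adaptation recentres the grid on the
posterior mode mu_v of the latent vector and rescales by a Cholesky square
root C of the posterior curvature tau_v; the weight correction
``w_k * det(C) * phi_r(alpha_k) / phi_r(a_k)`` makes the adapted sum a
quadrature approximation of the same prior-weighted integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import roots_hermite

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class QuadratureRule:
    """One-dimensional rule: q abscissas and standard-normal weights."""

    q: int
    abscissas: np.ndarray
    weights: np.ndarray


@dataclass(frozen=True)
class ProductGrid:
    """All q^r nodes of an r-dimensional tensor-product rule."""

    r: int
    q: int
    nodes: np.ndarray  # (q^r, r)
    weights: np.ndarray  # (q^r,)


@dataclass(frozen=True)
class AdaptiveState:
    """Posterior mode and curvature (covariance) of the latent vector."""

    mode: np.ndarray  # (r,)
    curvature: np.ndarray  # (r, r), symmetric positive definite


def ghq_rule(q: int) -> QuadratureRule:
    """Gauss-Hermite rule rescaled to the N(0,1) weight.

    Exact for polynomial integrands of degree <= 2q-1 against the
    standard-normal density.
    """
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    a_star, w_star = roots_hermite(q)
    a = np.sqrt(2.0) * a_star
    w = w_star / np.sqrt(np.pi)
    # symmetrize away roundoff so the rule is exactly even
    a = 0.5 * (a - a[::-1])
    w = 0.5 * (w + w[::-1])
    return QuadratureRule(q=q, abscissas=a, weights=w)


def product_grid(rule: QuadratureRule, r: int) -> ProductGrid:
    """Tensor product of a 1-D rule over r dimensions (q^r nodes)."""
    if r < 1:
        raise ValueError(f"r must be >= 1, got {r}")
    grids = np.meshgrid(*([rule.abscissas] * r), indexing="ij")
    nodes = np.stack([g.ravel() for g in grids], axis=1)
    wgrids = np.meshgrid(*([rule.weights] * r), indexing="ij")
    weights = np.prod(np.stack([g.ravel() for g in wgrids], axis=1), axis=1)
    return ProductGrid(r=r, q=rule.q, nodes=nodes, weights=weights)


def _log_std_normal(x: np.ndarray) -> np.ndarray:
    """log phi_r at rows of x, shape (..., r)."""
    r = x.shape[-1]
    return -0.5 * (r * _LOG2PI + np.sum(x * x, axis=-1))


def adapt_rule(grid: ProductGrid, state: AdaptiveState) -> ProductGrid:
    """Recentre/rescale a product grid at a posterior mode and curvature.

    Nodes become ``alpha_k = mu + C a_k`` with C the (lower) Cholesky factor
    of tau; weights pick up ``det(C) * phi_r(alpha_k)/phi_r(a_k)`` so that
    sums against exp(conditional loglik) still approximate the
    prior-weighted marginal likelihood.
    """
    tau = np.asarray(state.curvature, dtype=float)
    if tau.shape != (grid.r, grid.r):
        raise ValueError("curvature has wrong shape for the grid dimension")
    if not np.allclose(tau, tau.T):
        raise np.linalg.LinAlgError("curvature matrix is not symmetric")
    C = np.linalg.cholesky(tau)  # raises LinAlgError if not PD
    mu = np.asarray(state.mode, dtype=float)
    alpha = mu[None, :] + grid.nodes @ C.T
    log_corr = (
        np.sum(np.log(np.diag(C)))
        + _log_std_normal(alpha)
        - _log_std_normal(grid.nodes)
    )
    return ProductGrid(r=grid.r, q=grid.q, nodes=alpha, weights=grid.weights * np.exp(log_corr))


def locate_posterior_mode(params, observation, spec, link=None) -> AdaptiveState:
    """Mode and curvature of ``log phi(v) + log f(y | v)`` for one child.

    ``params`` is a :class:`~mimicgsem.likelihood.ParameterVector`,
    ``observation`` a single-row mapping/Series with indicator and covariate
    values. The objective is concave for all three supported links, so the
    safeguarded Newton iteration converges to the unique mode; the returned
    curvature is the negative inverse Hessian there (the Gaussian
    approximation's covariance).
    """
    from .likelihood import _single_observation_mode  # lazy: avoids an import cycle

    return _single_observation_mode(params, observation, spec, link=link)
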