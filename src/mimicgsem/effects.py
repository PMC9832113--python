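"""Direct / indirect / total effect decomposition on the log-odds scale.

With beta1 the structural mediator->outcome coefficient (morbidity <-
malnutrition), beta2 a covariate's path into the mediator and beta3 its path
into the outcome, the product-of-coefficients decomposition is

    indirect = beta1 * beta2,   total = beta3 + beta1 * beta2,

and adjusted odds ratios are the exponentials, so AOR_total =
AOR_direct * AOR_indirect exactly. Confidence intervals for the products use
the delta method on the estimated parameter covariance by default, with a
seeded nonparametric bootstrap as the alternative.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model_spec import ModelSpec

Z95 = 1.96


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "**" if p < 0.001 else ("*" if p < 0.05 else "")


@dataclass(frozen=True)
class EffectEstimate:
    """One covariate level's mediated effect decomposition.

    Log-odds effects satisfy total = direct + indirect exactly; the AOR
    properties are their exponentials, so the multiplicative identity
    aor_total = aor_direct * aor_indirect holds before any rounding.
    """

    covariate_level: str
    direct: float
    indirect: float
    se_direct: Optional[float] = None
    se_indirect: Optional[float] = None
    se_total: Optional[float] = None

    @property
    def total(self) -> float:
        return self.direct + self.indirect

    @property
    def aor_direct(self) -> float:
        return float(np.exp(self.direct))

    @property
    def aor_indirect(self) -> float:
        return float(np.exp(self.indirect))

    @property
    def aor_total(self) -> float:
        return float(np.exp(self.total))

    def _ci(self, est: float, se: Optional[float]) -> Optional[Tuple[float, float]]:
        if se is None:
            return None
        return (est - Z95 * se, est + Z95 * se)

    @property
    def ci_direct(self):
        return self._ci(self.direct, self.se_direct)

    @property
    def ci_indirect(self):
        return self._ci(self.indirect, self.se_indirect)

    @property
    def ci_total(self):
        return self._ci(self.total, self.se_total)

    def aor_ci(self, which: str):
        ci = getattr(self, f"ci_{which}")
        if ci is None:
            return None
        return (float(np.exp(ci[0])), float(np.exp(ci[1])))


@dataclass
class EffectTable:
    """All covariate-level decompositions from one fit."""

    rows: list

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for e in self.rows:
            cov, _, level = e.covariate_level.partition("=")
            rec = {
                "covariate": cov, "level": level,
                "covariate_level": e.covariate_level,
                "direct": e.direct, "indirect": e.indirect, "total": e.total,
                "aor_direct": e.aor_direct, "aor_indirect": e.aor_indirect,
                "aor_total": e.aor_total,
            }
            for which in ("direct", "indirect", "total"):
                ci = e.aor_ci(which)
                rec[f"aor_{which}_lo"] = np.nan if ci is None else ci[0]
                rec[f"aor_{which}_hi"] = np.nan if ci is None else ci[1]
                se = getattr(e, f"se_{which}", None)
                eff = getattr(e, which)
                if se is None or not np.isfinite(se):
                    p = np.nan
                elif se == 0:
                    p = np.nan if eff == 0 else 0.0
                else:
                    p = 2.0 * norm.sf(abs(eff) / se)
                rec[f"stars_{which}"] = _stars(p)
            recs.append(rec)
        return pd.DataFrame(recs)


def _mediation_paths(spec: ModelSpec):
    if len(spec.latent_paths) != 1:
        raise ValueError("effect decomposition requires exactly one latent path")
    mediator, outcome = spec.latent_paths[0]
    return mediator, outcome


def _col_name(covariate_level) -> str:
    if isinstance(covariate_level, (tuple, list)):
        return f"{covariate_level[0]}={covariate_level[1]}"
    return str(covariate_level)


def decompose(fit_result, covariate_level, spec: Optional[ModelSpec] = None) -> EffectEstimate:
    """Point decomposition for one covariate level (``"cov=level"`` or tuple).

    A missing path contributes a coefficient of exactly 0, so a covariate
    with no path into the mediator has indirect = 0 and total = direct.
    """
    spec = spec or fit_result.spec
    mediator, outcome = _mediation_paths(spec)
    col = _col_name(covariate_level)
    known = {
        c for cv in spec.covariates for c in cv.design_columns()
    }
    if col not in known:
        raise KeyError(f"unknown covariate level {col!r}")
    layout = fit_result.params.layout
    beta1 = float(fit_result.params[f"struct:{outcome}<-{mediator}"])
    n2, n3 = f"reg:{mediator}<-{col}", f"reg:{outcome}<-{col}"
    beta2 = float(fit_result.params[n2]) if n2 in layout else 0.0
    beta3 = float(fit_result.params[n3]) if n3 in layout else 0.0
    return EffectEstimate(covariate_level=col, direct=beta3, indirect=beta1 * beta2)


def effect_ci(fit_result, estimate: EffectEstimate, method: str = "delta",
              B: int = 200, seed: int = 0, data: Optional[pd.DataFrame] = None) -> EffectEstimate:
    """Attach 95% CIs to a decomposition (delta method or bootstrap)."""
    if method == "delta":
        return _delta_ci(fit_result, estimate)
    if method == "bootstrap":
        return _bootstrap_ci(fit_result, estimate, B=B, seed=seed, data=data)
    raise ValueError("method must be 'delta' or 'bootstrap'")


def _param_cov(fit_result, names):
    """Covariance submatrix over parameter names; absent names are constants."""
    if fit_result.vcov is None:
        from .estimation import standard_errors

        standard_errors(fit_result)
    layout = fit_result.params.layout
    k = len(names)
    V = np.zeros((k, k))
    idx = [layout.index(n) if n in layout else None for n in names]
    for a in range(k):
        for b in range(k):
            if idx[a] is not None and idx[b] is not None:
                V[a, b] = fit_result.vcov[idx[a], idx[b]]
    return V


def _delta_ci(fit_result, est: EffectEstimate) -> EffectEstimate:
    spec = fit_result.spec
    mediator, outcome = _mediation_paths(spec)
    col = est.covariate_level
    names = [f"struct:{outcome}<-{mediator}", f"reg:{mediator}<-{col}", f"reg:{outcome}<-{col}"]
    layout = fit_result.params.layout
    b1 = float(fit_result.params[names[0]])
    b2 = float(fit_result.params[names[1]]) if names[1] in layout else 0.0
    V = _param_cov(fit_result, names)
    var_dir = V[2, 2]
    g_ind = np.array([b2, b1, 0.0])
    var_ind = float(g_ind @ V @ g_ind)
    g_tot = np.array([b2, b1, 1.0])
    var_tot = float(g_tot @ V @ g_tot)
    return replace(
        est,
        se_direct=float(np.sqrt(max(var_dir, 0.0))),
        se_indirect=float(np.sqrt(max(var_ind, 0.0))),
        se_total=float(np.sqrt(max(var_tot, 0.0))),
    )


@dataclass(frozen=True)
class _PercentileCI(EffectEstimate):
    """Bootstrap variant: CIs are stored percentile bounds, not +/- 1.96 se."""

    ci_direct_: Optional[Tuple[float, float]] = None
    ci_indirect_: Optional[Tuple[float, float]] = None
    ci_total_: Optional[Tuple[float, float]] = None
    n_success: int = 0
    n_failed: int = 0

    @property
    def ci_direct(self):
        return self.ci_direct_

    @property
    def ci_indirect(self):
        return self.ci_indirect_

    @property
    def ci_total(self):
        return self.ci_total_


def _bootstrap_ci(fit_result, est: EffectEstimate, B: int, seed: int,
                  data: Optional[pd.DataFrame]) -> EffectEstimate:
    from .estimation import fit as _fit

    ev = fit_result._evaluator
    if data is None:
        if ev is None:
            raise ValueError("bootstrap needs the original dataset")
        raise ValueError("pass the original dataset via data= for the bootstrap")
    rng = np.random.default_rng(seed)
    draws = {"direct": [], "indirect": [], "total": []}
    failed = 0
    for _ in range(B):
        idx = rng.integers(0, len(data), size=len(data))
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            fr = _fit(
                fit_result.spec, sample, link=fit_result.link, q=fit_result.q,
                adaptive=fit_result.adaptive, missing=fit_result.missing,
                start=fit_result.params, fix=fit_result.fixed,
            )
            e = decompose(fr, est.covariate_level)
            draws["direct"].append(e.direct)
            draws["indirect"].append(e.indirect)
            draws["total"].append(e.total)
        except Exception:
            failed += 1
    ok = len(draws["direct"])
    if ok < 0.8 * B:
        raise RuntimeError(f"too many bootstrap refit failures ({failed}/{B})")
    if failed:
        warnings.warn(f"{failed}/{B} bootstrap refits failed; CI uses {ok} resamples",
                      RuntimeWarning)

    def pci(xs):
        return (float(np.percentile(xs, 2.5)), float(np.percentile(xs, 97.5)))

    return _PercentileCI(
        covariate_level=est.covariate_level, direct=est.direct, indirect=est.indirect,
        ci_direct_=pci(draws["direct"]), ci_indirect_=pci(draws["indirect"]),
        ci_total_=pci(draws["total"]), n_success=ok, n_failed=failed,
    )


# ---------------------------------------------------------------------------
# display tables


def _fmt(aor: float, lo: float, hi: float, stars: str) -> str:
    return f"{aor:.2f}{stars} ({lo:.2f}-{hi:.2f})"


_CELL_RE = re.compile(r"([0-9.]+)(\*{0,2}) \(([0-9.]+)-([0-9.]+)\)")


def parse_cell(cell: str):
    """Recover (aor, lo, hi, stars) from a rendered table cell."""
    m = _CELL_RE.fullmatch(cell)
    if not m:
        raise ValueError(f"unparseable cell {cell!r}")
    return float(m.group(1)), float(m.group(3)), float(m.group(4)), m.group(2)


def render_effect_tables(fit_result, spec: Optional[ModelSpec] = None):
    """Two display tables of AORs with 95% CIs and significance stars.

    The first mirrors the direct-effects layout (rows: structural path and
    covariate levels vs reference; columns: the two latents; "-" where the
    spec has no path). The second gives indirect and total effects on the
    outcome latent via the mediator. Stars: ** p<0.001, * p<0.05 (two-sided
    Wald).
    """
    spec = spec or fit_result.spec
    if fit_result.se is None:
        from .estimation import standard_errors

        standard_errors(fit_result)
    mediator, outcome = _mediation_paths(spec)
    wald = fit_result.wald_table()
    layout = fit_result.params.layout

    def direct_cell(name):
        if name not in layout:
            return "-"
        row = wald.loc[name]
        return _fmt(row["aor"], row["aor_lo"], row["aor_hi"], row["stars"])

    rows = {}
    rows[mediator.capitalize()] = {
        mediator: "-",
        outcome: direct_cell(f"struct:{outcome}<-{mediator}"),
    }
    cov_cols = [
        (cv, col) for cv in spec.covariates for col in cv.design_columns()
        if f"reg:{mediator}<-{col}" in layout or f"reg:{outcome}<-{col}" in layout
    ]
    for cv, col in cov_cols:
        label = f"{cv.name} (ref: {cv.reference}): {col.split('=', 1)[1]}"
        rows[label] = {
            mediator: direct_cell(f"reg:{mediator}<-{col}"),
            outcome: direct_cell(f"reg:{outcome}<-{col}"),
        }
    direct_table = pd.DataFrame.from_dict(rows, orient="index")

    med_rows = {}
    for cv, col in cov_cols:
        est = effect_ci(fit_result, decompose(fit_result, col, spec), method="delta")
        label = f"{col} -> {outcome}"
        cells = {}
        for which in ("indirect", "total"):
            point = getattr(est, f"aor_{which}")
            lo, hi = est.aor_ci(which)
            se = getattr(est, f"se_{which}")
            eff = getattr(est, which)
            p = 2.0 * norm.sf(abs(eff) / se) if se and se > 0 else np.nan
            cells[which] = _fmt(point, lo, hi, _stars(p))
        med_rows[label] = cells
    mediated_table = pd.DataFrame.from_dict(med_rows, orient="index")
    return direct_table, mediated_table


def effect_table(fit_result, spec: Optional[ModelSpec] = None,
                 method: str = "delta", **ci_kwargs) -> EffectTable:
    """Machine-readable decomposition for every covariate level with a path."""
    spec = spec or fit_result.spec
    mediator, outcome = _mediation_paths(spec)
    layout = fit_result.params.layout
    rows = []
    for cv in spec.covariates:
        for col in cv.design_columns():
            if f"reg:{mediator}<-{col}" in layout or f"reg:{outcome}<-{col}" in layout:
                est = decompose(fit_result, col, spec)
                rows.append(effect_ci(fit_result, est, method=method, **ci_kwargs))
    return EffectTable(rows=rows)
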