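"""Dispersion estimation, grouped goodness-of-fit (T1), over/underdispersion
(T2), dispersion-adjusted inference and the (adjusted) Vuong comparison.

The T statistics group observations by the distinct observed values of y1.
For each group the 2-vector of deviations (group mean of y1 minus the group
average fitted marginal mean, group mean of y2 minus the group average
fitted conditional mean) enters a diagonal quadratic form.  Two denominator
conventions are supported:

``per_observation`` (default)
    the group-average fitted variance, sum(V_i)/n_g — the form the statistic
    is usually printed with.  The resulting T is an O(1) descriptive fit
    index whose magnitude does not grow with n.
``group_mean``
    the variance of the group mean, sum(V_i)/n_g**2.

Neither convention makes T1 exactly chi-square under the null: because the
grouping variable is the outcome itself, the marginal deviation
g - mean(lambda_hat | y1=g) carries a bias that does not vanish (the
conditional components, whose grouping is ancillary given y1, are the
well-behaved part).  The nominal chi-square reference with 2 df per group
(1 for the y1=0 group, whose conditional component is degenerate) is
reported for both conventions; see the methods note for calibration
evidence and guidance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .distributions import (poisson_logcdf, trunc_poisson_mean,
                            trunc_poisson_var)
from .regression import BivariateCountData, FitResult, ModelSpec

__all__ = [
    "GroupSummary",
    "DispersionEstimate",
    "TestResult",
    "VuongResult",
    "dispersion",
    "gof_T1",
    "dispersion_T2",
    "adjusted_inference",
    "vuong",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group ingredients of the grouped T statistics."""

    y1_level: int
    n_group: int
    mean_y1: float
    mean_y2: float
    fitted_mean1: float
    fitted_mean2: float
    fitted_var1: float
    fitted_var2: float
    component: float
    df: int


@dataclass(frozen=True)
class DispersionEstimate:
    """Pearson moment dispersion of the marginal (phi1) and conditional
    (phi2) parts; phi = 1 under the correct Poisson specification."""

    phi1: float
    phi2: float
    variant: str
    n_used1: int
    n_used2: int
    p_used: int


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    per_group: list[GroupSummary] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class VuongResult:
    raw_V: float
    adjusted_V: float
    p_value: float
    favored: str  # "model_f" | "model_g" | "neither"
    degenerate: bool = False


def _fitted_rates(data: BivariateCountData, fit: FitResult):
    lam1 = np.exp(data.X @ fit.beta1)
    lam2 = np.exp(data.X @ fit.beta2)  # per-unit conditional rate
    return lam1, lam2


def _fitted_mv(data, fit, spec: ModelSpec):
    """Per-observation fitted means/variances of each part, honoring
    truncation by direct summation when the variant is truncated.

    The conditional entries are for Y2 | Y1 = y1_i (zero when y1_i = 0).
    """
    lam1, lam2 = _fitted_rates(data, fit)
    y1 = data.y1
    if spec.variant == "untruncated":
        mu1, v1 = lam1, lam1
        mu2 = lam2 * y1
        v2 = mu2.copy()
    else:
        b = spec.bounds
        mu1 = trunc_poisson_mean(lam1, b.k1)
        v1 = trunc_poisson_var(lam1, b.k1)
        mu2 = trunc_poisson_mean(lam2 * y1, b.k2)
        v2 = trunc_poisson_var(lam2 * y1, b.k2)
    return np.atleast_1d(mu1), np.atleast_1d(v1), np.atleast_1d(mu2), np.atleast_1d(v2)


def trunc_corrected_mv(lam, k: int):
    """Truncated mean/variance via the correction-factor route (cross-check).

    alpha = h(k, lam) / H(k, lam) with h the pmf at k and H the cdf at k;
    delta = -lam * alpha; mu_t = lam + delta and
    V_t = lam - delta * (mu_t - k - 1).
    """
    lam = np.asarray(lam, dtype=float)
    h = stats.poisson.pmf(k, lam)
    H = stats.poisson.cdf(k, lam)
    alpha = np.divide(h, H, out=np.zeros_like(lam), where=H > 0)
    delta = -lam * alpha
    mu = lam + delta
    V = lam - delta * (mu - k - 1.0)
    return mu, V


def dispersion(data: BivariateCountData, fit: FitResult,
               spec: ModelSpec | None = None) -> DispersionEstimate:
    """Method-of-moments (Pearson) dispersion for each part.

    phi_r = 1/(n-p) * sum (y_ri - mu_ri)^2 / V_ri with p the number of
    fitted coefficients of that part; the conditional part runs over rows
    with y1 > 0.  For the truncated variant mu and V are the direct
    truncated-summation moments.
    """
    spec = spec or fit.spec
    if not fit.converged:
        raise ValueError("dispersion requires a converged fit")
    mu1, v1, mu2, v2 = _fitted_mv(data, fit, spec)
    p = fit.q
    n1 = data.n
    phi1 = float(np.sum((data.y1 - mu1) ** 2 / v1) / (n1 - p))
    pos = (data.y1 > 0) & (v2 > 0)
    n2 = int(pos.sum())
    if n2 <= p:
        raise ValueError("too few rows with y1 > 0 for conditional dispersion")
    phi2 = float(np.sum((data.y2[pos] - mu2[pos]) ** 2 / v2[pos]) / (n2 - p))
    return DispersionEstimate(phi1=phi1, phi2=phi2, variant=spec.variant,
                              n_used1=n1, n_used2=n2, p_used=p)


def _grouped_T(data, fit, spec, denominator: str, phi1: float, phi2: float):
    """Shared machinery of T1 (phi=1) and T2 (dispersion-scaled)."""
    if denominator not in ("per_observation", "group_mean"):
        raise ValueError("denominator must be 'per_observation' or 'group_mean'")
    mu1, v1, mu2, v2 = _fitted_mv(data, fit, spec)
    levels = np.unique(data.y1)
    groups: list[GroupSummary] = []
    warns: list[str] = []
    total = 0.0
    df = 0
    for g in levels:
        m = data.y1 == g
        ng = int(m.sum())
        gm1, gv1 = float(mu1[m].mean()), float(v1[m].sum())
        gm2, gv2 = float(mu2[m].mean()), float(v2[m].sum())
        ybar1 = float(g)
        ybar2 = float(data.y2[m].mean())
        scale = ng if denominator == "per_observation" else ng * ng
        comp = 0.0
        gdf = 0
        d1 = ybar1 - phi1 * gm1
        denom1 = phi1 * gv1 / scale
        if denom1 > 0:
            comp += d1 * d1 / denom1
            gdf += 1
        else:
            warns.append(f"group y1={g}: zero marginal variance, component skipped")
        if g > 0 and gv2 > 0:
            d2 = ybar2 - phi2 * gm2
            denom2 = phi2 * gv2 / scale
            comp += d2 * d2 / denom2
            gdf += 1
        elif g > 0:
            warns.append(f"group y1={g}: zero conditional variance, component skipped")
        groups.append(GroupSummary(int(g), ng, ybar1, ybar2, gm1, gm2,
                                   gv1 / ng, gv2 / ng, comp, gdf))
        total += comp
        df += gdf
    p_value = float(stats.chi2.sf(total, df)) if df > 0 else float("nan")
    return TestResult(float(total), int(df), p_value, groups, warns)


def gof_T1(data: BivariateCountData, fit: FitResult, spec: ModelSpec | None = None,
           denominator: str = "per_observation") -> TestResult:
    """Grouped goodness-of-fit statistic T1.

    Groups are the observed distinct y1 values; each contributes the
    squared marginal and conditional deviations scaled by fitted variances
    (2 df, or 1 df for the y1=0 group whose conditional law is degenerate).
    The p-value uses the nominal chi-square reference; see the module
    docstring for its caveats.
    """
    spec = spec or fit.spec
    return _grouped_T(data, fit, spec, denominator, 1.0, 1.0)


def dispersion_T2(data: BivariateCountData, fit: FitResult,
                  disp: DispersionEstimate | None = None,
                  spec: ModelSpec | None = None,
                  denominator: str = "per_observation") -> TestResult:
    """Over/underdispersion statistic T2: T1 with dispersion-scaled means
    (mu* = phi * mu) and variance denominators.  Collapses to T1 when
    phi1 = phi2 = 1."""
    spec = spec or fit.spec
    if disp is None:
        disp = dispersion(data, fit, spec)
    return _grouped_T(data, fit, spec, denominator, disp.phi1, disp.phi2)


def adjusted_inference(fit: FitResult, disp: DispersionEstimate) -> FitResult:
    """Fill dispersion-adjusted standard errors and p-values on the fit.

    se_adj = sqrt(phi_r) * se blockwise; underdispersion (phi < 1) shrinks
    the standard errors.  Returns the same FitResult, mutated.
    """
    if fit.se is None:
        raise ValueError("fit carries no standard errors to adjust")
    scale = np.concatenate([np.full(fit.q, np.sqrt(disp.phi1)),
                            np.full(fit.q, np.sqrt(disp.phi2))])
    fit.se_adj = fit.se * scale
    fit.z_adj = fit.params / fit.se_adj
    fit.p_adj = 2 * stats.norm.sf(np.abs(fit.z_adj))
    return fit


def _per_obs_loglik(data: BivariateCountData, fit: FitResult) -> np.ndarray:
    """Per-observation log density under a fitted model (either variant)."""
    lam1, lam2 = _fitted_rates(data, fit)
    y1, y2 = data.y1, data.y2
    with np.errstate(divide="ignore"):
        lp = stats.poisson.logpmf(y1, lam1) + stats.poisson.logpmf(y2, lam2 * y1)
    if fit.spec.variant == "right_truncated":
        b = fit.spec.bounds
        lp -= poisson_logcdf(b.k1, lam1)
        pos = y1 > 0
        lp[pos] -= poisson_logcdf(b.k2, lam2[pos] * y1[pos])
    return lp


def vuong(data: BivariateCountData, fit_f: FitResult, fit_g: FitResult,
          crit: float = 1.96) -> VuongResult:
    """Vuong non-nested comparison of two fitted models on the same data.

    m_i = ln f_i - ln g_i; raw V = sqrt(n) * mean(m) / sd(m) (population
    sd).  The adjusted statistic applies a Schwarz correction, subtracting
    ((p - q)/2) ln n from sum(m_i).  V > crit favors model f, V < -crit
    favors model g.
    """
    if fit_f.n != data.n or fit_g.n != data.n:
        raise ValueError("both fits must come from the given data")
    n = data.n
    m = _per_obs_loglik(data, fit_f) - _per_obs_loglik(data, fit_g)
    s = float(np.std(m))
    if s < 1e-12:
        return VuongResult(0.0, 0.0, 1.0, "neither", degenerate=True)
    raw = float(np.sum(m) / (np.sqrt(n) * s))
    corr = (len(fit_f.params) - len(fit_g.params)) / 2.0 * np.log(n)
    adj = float((np.sum(m) - corr) / (np.sqrt(n) * s))
    favored = "model_f" if adj > crit else ("model_g" if adj < -crit else "neither")
    p = float(2 * stats.norm.sf(abs(adj)))
    return VuongResult(raw, adj, p, favored)
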