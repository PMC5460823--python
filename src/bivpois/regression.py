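"""Maximum-likelihood fitting of the bivariate Poisson-Poisson regression.

Both outcomes get log links on the same design matrix:
``ln lambda1 = x' beta1`` and ``ln lambda2 = x' beta2``, so the marginal mean
of Y1 is lambda1 and the conditional mean of Y2 given y1 is lambda2 * y1
(hence E Y2 = lambda1 * lambda2 at a covariate point).

For the untruncated model the log-likelihood separates: beta1 is a Poisson
regression of y1 on X, and beta2 a Poisson regression of y2 on X with offset
ln(y1) over the rows with y1 > 0 (rows with y1 = 0 carry no information
about beta2).  The right-truncated model adds per-observation normalizing
terms ln c1 + ln c2 and is maximized by quasi-Newton starting from the
untruncated estimates; the score has the closed form (y - mu_trunc) x for
each part, with mu_trunc the truncated mean.

Standard errors come from the numerically differentiated observed
information at the optimum (central differences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess3

from .distributions import (TruncationBounds, log_trunc_poisson_pmf,
                            trunc_poisson_mean)

__all__ = [
    "BivariateCountData",
    "ModelSpec",
    "FitResult",
    "CorrelationEstimate",
    "LRTestResult",
    "loglik_untruncated",
    "loglik_truncated",
    "fit",
    "fit_intercept_only",
    "lr_test",
    "correlation_estimate",
    "correlation_from_means",
]

_MAX_ETA = 700.0  # exp overflow guard on the linear predictor


@dataclass
class BivariateCountData:
    """Paired counts (y1, y2) with a shared design matrix.

    ``X`` carries a leading intercept column; ``columns`` names its columns
    (first entry "const").  Rows with y1 = 0 must have y2 = 0: the
    conditional law is degenerate at zero there.
    """

    y1: np.ndarray
    y2: np.ndarray
    X: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.y1 = np.asarray(self.y1)
        self.y2 = np.asarray(self.y2)
        self.X = np.asarray(self.X, dtype=float)
        for name, y in (("y1", self.y1), ("y2", self.y2)):
            if not np.issubdtype(y.dtype, np.integer):
                if not np.all(np.equal(np.mod(y, 1), 0)):
                    bad = np.flatnonzero(~np.equal(np.mod(y, 1), 0))[:10]
                    raise ValueError(f"{name} must be integer counts; offending rows {bad.tolist()}")
            if np.any(y < 0):
                raise ValueError(f"{name} must be non-negative")
        self.y1 = self.y1.astype(np.int64)
        self.y2 = self.y2.astype(np.int64)
        n = len(self.y1)
        if not (len(self.y2) == n and self.X.shape[0] == n):
            raise ValueError("y1, y2 and X must have equal length")
        if np.any(np.isnan(self.X)):
            raise ValueError("design matrix contains missing values")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("columns must name every design column")
        bad = (self.y1 == 0) & (self.y2 > 0)
        if np.any(bad):
            rows = np.flatnonzero(bad)[:10]
            raise ValueError(
                f"rows with y1=0 must have y2=0 (zero-probability rows {rows.tolist()})"
            )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, y1_col: str = "y1", y2_col: str = "y2",
                   covariate_cols: list[str] | None = None) -> "BivariateCountData":
        """Build from a tidy per-subject DataFrame, adding an intercept."""
        if covariate_cols is None:
            covariate_cols = [c for c in df.columns if c not in (y1_col, y2_col)]
        missing = [c for c in (y1_col, y2_col, *covariate_cols) if c not in df.columns]
        if missing:
            raise KeyError(f"columns not found: {missing}")
        sub = df[[y1_col, y2_col, *covariate_cols]]
        if sub.isna().any().any():
            raise ValueError("missing values present; refuse to drop silently")
        X = np.column_stack([np.ones(len(df)), sub[covariate_cols].to_numpy(float)]) \
            if covariate_cols else np.ones((len(df), 1))
        return cls(sub[y1_col].to_numpy(), sub[y2_col].to_numpy(), X,
                   ["const", *covariate_cols])

    def describe(self) -> dict:
        """Sample means and variances of the two outcomes (ddof=1)."""
        return {
            "n": int(len(self.y1)),
            "mean_y1": float(np.mean(self.y1)),
            "var_y1": float(np.var(self.y1, ddof=1)),
            "mean_y2": float(np.mean(self.y2)),
            "var_y2": float(np.var(self.y2, ddof=1)),
        }

    @property
    def n(self) -> int:
        return len(self.y1)


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant to fit, and the truncation bounds if truncated."""

    variant: str = "untruncated"  # or "right_truncated"
    bounds: TruncationBounds | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("untruncated", "right_truncated"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "untruncated" and self.bounds is not None:
            raise ValueError("bounds are only meaningful for the truncated variant")


@dataclass
class FitResult:
    """MLE output for one model variant.

    ``params`` stacks (beta1, beta2); ``se``, ``zvalues``, ``pvalues`` align
    with it.  ``se_adj``/``z_adj``/``p_adj`` are filled by
    :func:`bivpois.diagnostics.adjusted_inference`.
    """

    params: np.ndarray
    loglik: float
    vcov: np.ndarray | None
    names: list[str]
    spec: ModelSpec
    n: int
    converged: bool
    n_iter: int
    se_adj: np.ndarray | None = None
    z_adj: np.ndarray | None = None
    p_adj: np.ndarray | None = None

    @property
    def q(self) -> int:  # coefficients per part
        return len(self.params) // 2

    @property
    def beta1(self) -> np.ndarray:
        return self.params[: self.q]

    @property
    def beta2(self) -> np.ndarray:
        return self.params[self.q:]

    @property
    def se(self) -> np.ndarray | None:
        if self.vcov is None:
            return None
        return np.sqrt(np.diag(self.vcov))

    @property
    def zvalues(self) -> np.ndarray | None:
        return None if self.se is None else self.params / self.se

    @property
    def pvalues(self) -> np.ndarray | None:
        z = self.zvalues
        return None if z is None else 2 * stats.norm.sf(np.abs(z))

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.params)

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + len(self.params) * np.log(self.n)

    def summary_frame(self) -> pd.DataFrame:
        d = {"estimate": self.params}
        if self.se is not None:
            d.update({"se": self.se, "z": self.zvalues, "p": self.pvalues})
        if self.se_adj is not None:
            d.update({"se_adj": self.se_adj, "z_adj": self.z_adj, "p_adj": self.p_adj})
        part = ["marginal"] * self.q + ["conditional"] * self.q
        return pd.DataFrame(d, index=pd.MultiIndex.from_arrays(
            [part, self.names * 2], names=["part", "term"]))


@dataclass(frozen=True)
class CorrelationEstimate:
    """Model-implied correlation of (Y1, Y2) and its standard error."""

    r: float
    se_r: float


@dataclass(frozen=True)
class LRTestResult:
    statistic: float
    df: int
    p_value: float


def _linpred(X, beta):
    eta = X @ beta
    if not np.all(np.isfinite(eta)) or np.any(np.abs(eta) > _MAX_ETA):
        raise FloatingPointError("non-finite or overflowing linear predictor")
    return eta


def loglik_untruncated(beta1, beta2, data: BivariateCountData) -> float:
    """Exact untruncated log-likelihood, factorial constants included.

    Per row: y1*eta1 + y2*eta2 - e^eta1 - y1*e^eta2 + y2*ln y1
    - ln y1! - ln y2!, with y2*ln y1 := 0 when y1 = 0.
    """
    beta1 = np.asarray(beta1, dtype=float)
    beta2 = np.asarray(beta2, dtype=float)
    y1, y2, X = data.y1, data.y2, data.X
    eta1 = _linpred(X, beta1)
    eta2 = _linpred(X, beta2)
    ll = y1 * eta1 - np.exp(eta1) - special.gammaln(y1 + 1.0)
    pos = y1 > 0
    lam2 = np.exp(eta2)
    ll_pos = (y2[pos] * eta2[pos] - lam2[pos] * y1[pos]
              + y2[pos] * np.log(y1[pos]) - special.gammaln(y2[pos] + 1.0))
    return float(ll.sum() + ll_pos.sum())


def loglik_truncated(beta1, beta2, data: BivariateCountData,
                     bounds: TruncationBounds) -> float:
    """Right-truncated log-likelihood: untruncated terms + ln c1 + ln c2,
    plus the y2*ln(y1) - ln y1! reparameterization constants.

    Evaluated as the sum of truncated Poisson log pmfs in a form where the
    rate term common to the pmf and its normalizer cancels analytically, so
    the value stays accurate however far the optimizer strays.
    """
    if np.any(data.y1 > bounds.k1) or np.any(data.y2 > bounds.k2):
        raise ValueError("observed counts exceed the truncation bounds")
    beta1 = np.asarray(beta1, dtype=float)
    beta2 = np.asarray(beta2, dtype=float)
    eta1 = _linpred(data.X, beta1)
    eta2 = _linpred(data.X, beta2)
    y1, y2 = data.y1, data.y2
    ll = np.sum(log_trunc_poisson_pmf(y1, np.exp(eta1), bounds.k1))
    pos = y1 > 0
    if np.any(pos):
        ll += np.sum(log_trunc_poisson_pmf(
            y2[pos], np.exp(eta2[pos]) * y1[pos], bounds.k2))
    return float(ll)


def _loglik_for_spec(params, data, spec: ModelSpec) -> float:
    q = data.X.shape[1]
    if spec.variant == "untruncated":
        return loglik_untruncated(params[:q], params[q:], data)
    return loglik_truncated(params[:q], params[q:], data, spec.bounds)


def _trunc_score(params, data, bounds: TruncationBounds):
    """Analytic score of the truncated log-likelihood.

    d lnL / d beta1 = X' (y1 - mu_t1),  mu_t1 = E[Y1 | Y1 <= k1] at lam1_i;
    d lnL / d beta2 = X' (y2 - mu_t2) over rows y1>0,
                      mu_t2 = E[Y2 | Y2 <= k2] at lam2_i * y1_i.
    """
    q = data.X.shape[1]
    eta1 = _linpred(data.X, params[:q])
    eta2 = _linpred(data.X, params[q:])
    mu_t1 = trunc_poisson_mean(np.exp(eta1), bounds.k1)
    g1 = data.X.T @ (data.y1 - mu_t1)
    pos = data.y1 > 0
    mu_t2 = np.zeros(data.n)
    if np.any(pos):
        mu_t2[pos] = trunc_poisson_mean(np.exp(eta2[pos]) * data.y1[pos], bounds.k2)
    g2 = data.X.T @ (data.y2 - mu_t2)
    return np.concatenate([g1, g2])


def _fit_untruncated_parts(data: BivariateCountData):
    """Two-stage Poisson GLM fit exploiting the likelihood separation."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m1 = sm.GLM(data.y1, data.X, family=sm.families.Poisson()).fit()
        pos = data.y1 > 0
        if pos.sum() <= data.X.shape[1]:
            raise ValueError("too few rows with y1 > 0 to estimate the conditional part")
        m2 = sm.GLM(data.y2[pos], data.X[pos], family=sm.families.Poisson(),
                    offset=np.log(data.y1[pos])).fit()
    if not (m1.converged and m2.converged):
        warnings.warn("Poisson GLM stage did not converge", RuntimeWarning)
    return m1, m2


def fit(data: BivariateCountData, spec: ModelSpec | None = None,
        compute_se: bool = True, maxiter: int = 500) -> FitResult:
    """Maximize the chosen log-likelihood over (beta1, beta2).

    The untruncated likelihood separates into two Poisson GLMs; the
    truncated variant is maximized by L-BFGS with the analytic score,
    seeded at the untruncated estimates.  If the spec omits truncation
    bounds they default to (max y1, max y2) and are recorded in the result.
    """
    if spec is None:
        spec = ModelSpec()
    q = data.X.shape[1]
    if data.n <= 2 * q:
        raise ValueError("need n > 2(p+1) observations")
    if np.linalg.matrix_rank(data.X) < q:
        raise ValueError("design matrix is rank deficient")

    m1, m2 = _fit_untruncated_parts(data)
    start = np.concatenate([m1.params, m2.params])

    if spec.variant == "untruncated":
        params = start
        converged = bool(m1.converged and m2.converged)
        n_iter = int(getattr(m1, "fit_history", {}).get("iteration", 0) or 0)
    else:
        bounds = spec.bounds
        if bounds is None:
            bounds = TruncationBounds(int(data.y1.max()), int(data.y2.max()))
            spec = ModelSpec("right_truncated", bounds)
        if bounds.k1 < data.y1.max() or bounds.k2 < data.y2.max():
            raise ValueError("truncation bounds below observed maxima")

        def nll(p):
            try:
                val = -_loglik_for_spec(p, data, spec)
            except FloatingPointError:
                return np.inf
            return val if np.isfinite(val) else np.inf

        def grad(p):
            try:
                return -_trunc_score(p, data, bounds)
            except FloatingPointError:
                return np.zeros_like(p)

        res = optimize.minimize(nll, start, jac=grad, method="L-BFGS-B",
                                options={"maxiter": maxiter, "ftol": 1e-12,
                                         "gtol": 1e-7})
        params = res.x
        converged = bool(res.success)
        n_iter = int(res.nit)
        if not converged:
            warnings.warn(f"truncated fit did not converge: {res.message}",
                          RuntimeWarning)

    ll = _loglik_for_spec(params, data, spec)
    vcov = None
    if compute_se:
        H = approx_hess3(params, lambda p: _loglik_for_spec(p, data, spec))
        H = 0.5 * (H + H.T)
        try:
            vcov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            warnings.warn("observed information is singular; no covariance",
                          RuntimeWarning)
        if vcov is not None and np.any(np.diag(vcov) <= 0):
            warnings.warn("observed information not positive definite",
                          RuntimeWarning)
        if vcov is not None:
            vcov = 0.5 * (vcov + vcov.T)
    return FitResult(params=params, loglik=ll, vcov=vcov, names=list(data.columns),
                     spec=spec, n=data.n, converged=converged, n_iter=n_iter)


def fit_intercept_only(data: BivariateCountData, spec: ModelSpec | None = None,
                       compute_se: bool = True) -> FitResult:
    """Fit the reduced (intercept-only) model on the same data/variant."""
    reduced = BivariateCountData(data.y1, data.y2, np.ones((data.n, 1)), ["const"])
    return fit(reduced, spec, compute_se=compute_se)


def lr_test(full: FitResult, reduced: FitResult) -> LRTestResult:
    """Likelihood-ratio test of all slope coefficients being zero.

    statistic = -2 (lnL_reduced - lnL_full), chi-square with 2p df where p
    is the number of slope covariates in the full model.
    """
    if full.spec.variant != reduced.spec.variant:
        raise ValueError("models must share the same variant")
    if full.n != reduced.n:
        raise ValueError("models must be fitted on the same data")
    df = len(full.params) - len(reduced.params)
    if df < 0:
        raise ValueError("reduced model must be nested with fewer parameters")
    stat = -2.0 * (reduced.loglik - full.loglik)
    if stat < -1e-6:
        warnings.warn("reduced log-likelihood exceeds full; check convergence",
                      RuntimeWarning)
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LRTestResult(float(stat), int(df), p)


def correlation_from_means(ybar1: float, ybar2: float, n: int) -> CorrelationEstimate:
    """Moment correlation estimate r = sqrt(l/(l+1)), l = ybar2/ybar1.

    The standard error is the literal printed formula
    se(r) = sqrt( ybar1^2 / {4 n (ybar1 + ybar2)}^3 ), whose bracket
    placement in the source is ambiguous; the cube is applied to the whole
    braced denominator here.
    """
    if ybar1 <= 0:
        raise ValueError("ybar1 must be positive")
    if ybar2 < 0:
        raise ValueError("ybar2 must be non-negative")
    lam2 = ybar2 / ybar1
    r = float(np.sqrt(lam2 / (lam2 + 1.0)))
    se = float(np.sqrt(ybar1 ** 2 / (4.0 * n * (ybar1 + ybar2)) ** 3))
    return CorrelationEstimate(r=r, se_r=se)


def correlation_estimate(data: BivariateCountData) -> CorrelationEstimate:
    """Correlation of (Y1, Y2) implied by the sample means of a dataset."""
    if np.all(data.y1 == 0):
        raise ValueError("correlation undefined when all y1 are zero")
    return correlation_from_means(float(np.mean(data.y1)), float(np.mean(data.y2)),
                                  data.n)
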