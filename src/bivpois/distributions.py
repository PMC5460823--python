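"""Untruncated and right-truncated bivariate Poisson-Poisson distributions.

The model is built by the marginal-conditional approach: Y1 is Poisson with
rate ``lambda1`` and, given Y1 = y1, Y2 is Poisson with rate
``lambda2 * y1``.  The joint pmf is therefore

    g(y1, y2) = e^{-l1} l1^{y1} / y1!  *  e^{-l2 y1} (l2 y1)^{y2} / y2!

with the convention 0^0 = 1, so the conditional law at y1 = 0 is a point
mass at y2 = 0.  Right truncation restricts Y1 to {0..k1} and Y2 | y1 to
{0..k2}; probabilities are renormalized by the reciprocal Poisson cdf at the
bound (constants c1 and c2 below).

All pmf evaluation is done in log space.  Truncated moments are defined by
direct finite summation over the truncated support; the incomplete-gamma
identity for the truncated mean is provided as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "RatePair",
    "TruncationBounds",
    "MomentSet",
    "SupportError",
    "joint_pmf",
    "log_joint_pmf",
    "trunc_norm_c1",
    "trunc_norm_c2",
    "trunc_joint_pmf",
    "log_trunc_joint_pmf",
    "trunc_moments",
    "trunc_poisson_mean",
    "trunc_poisson_var",
    "trunc_mean_incgamma",
    "marginal_pmf_y2",
    "sample",
]


@dataclass(frozen=True)
class RatePair:
    """Rates of the bivariate Poisson-Poisson law.

    ``lambda1`` is the marginal Poisson rate of Y1; ``lambda2`` is the
    per-unit conditional rate: Y2 | Y1=y1 is Poisson(lambda2 * y1).
    """

    lambda1: float
    lambda2: float

    def __post_init__(self) -> None:
        if not (self.lambda1 > 0 and np.isfinite(self.lambda1)):
            raise ValueError(f"lambda1 must be a positive finite real, got {self.lambda1}")
        if not (self.lambda2 > 0 and np.isfinite(self.lambda2)):
            raise ValueError(f"lambda2 must be a positive finite real, got {self.lambda2}")


@dataclass(frozen=True)
class TruncationBounds:
    """Right-truncation points: Y1 has support {0..k1}, Y2|y1 has {0..k2}."""

    k1: int
    k2: int

    def __post_init__(self) -> None:
        for name in ("k1", "k2"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")


@dataclass(frozen=True)
class MomentSet:
    """Mean/variance of Y1 and of Y2 given a fixed y1 (possibly truncated)."""

    mean1: float
    var1: float
    cond_mean2: float
    cond_var2: float


class SupportError(ValueError):
    """Point lies outside the truncated support (distinct from probability 0)."""


def _check_count(y, name: str):
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.integer):
        if not np.all(np.equal(np.mod(y, 1), 0)):
            raise ValueError(f"{name} must be integer-valued")
        y = y.astype(np.int64)
    if np.any(y < 0):
        raise ValueError(f"{name} must be non-negative")
    return y


def log_joint_pmf(y1, y2, rates: RatePair):
    """Log joint pmf; vectorized over ``y1``/``y2``. -inf where y1=0, y2>0."""
    y1 = _check_count(y1, "y1")
    y2 = _check_count(y2, "y2")
    with np.errstate(divide="ignore"):
        lp1 = stats.poisson.logpmf(y1, rates.lambda1)
        # conditional rate lambda2*y1 is 0 when y1=0: point mass at y2=0
        lp2 = stats.poisson.logpmf(y2, rates.lambda2 * y1)
    return lp1 + lp2


def joint_pmf(y1, y2, rates: RatePair):
    """Joint pmf of (Y1, Y2) under the untruncated model."""
    return np.exp(log_joint_pmf(y1, y2, rates))


def trunc_norm_c1(lambda1: float, k1: int) -> float:
    """Normalizer c1 = 1 / P(Poisson(lambda1) <= k1); >= 1."""
    if not (lambda1 > 0):
        raise ValueError("lambda1 must be positive")
    if not (int(k1) == k1 and k1 >= 0):
        raise ValueError("k1 must be a non-negative integer")
    return float(1.0 / stats.poisson.cdf(k1, lambda1))


def trunc_norm_c2(lambda2: float, y1: int, k2: int) -> float:
    """Normalizer c2(y1) = 1 / P(Poisson(lambda2*y1) <= k2); equals 1 at y1=0."""
    if not (lambda2 > 0):
        raise ValueError("lambda2 must be positive")
    y1 = int(_check_count(y1, "y1"))
    if not (int(k2) == k2 and k2 >= 0):
        raise ValueError("k2 must be a non-negative integer")
    if y1 == 0:
        return 1.0
    return float(1.0 / stats.poisson.cdf(k2, lambda2 * y1))


def log_trunc_joint_pmf(y1, y2, rates: RatePair, bounds: TruncationBounds):
    """Log pmf of the right-truncated joint law on {0..k1} x {0..k2}."""
    y1 = _check_count(y1, "y1")
    y2 = _check_count(y2, "y2")
    if np.any(y1 > bounds.k1) or np.any(y2 > bounds.k2):
        raise SupportError(
            f"point outside truncated support k1={bounds.k1}, k2={bounds.k2}"
        )
    with np.errstate(divide="ignore"):
        log_c1 = -stats.poisson.logcdf(bounds.k1, rates.lambda1)
        log_c2 = np.where(
            y1 > 0, -stats.poisson.logcdf(bounds.k2, rates.lambda2 * y1), 0.0
        )
    return log_joint_pmf(y1, y2, rates) + log_c1 + log_c2


def trunc_joint_pmf(y1, y2, rates: RatePair, bounds: TruncationBounds):
    """Right-truncated joint pmf; sums to 1 over its finite support."""
    return np.exp(log_trunc_joint_pmf(y1, y2, rates, bounds))


def _trunc_poisson_logw(lam, k: int):
    """Log weights of Poisson(lam) on {0..k}, unnormalized; lam array-like."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    y = np.arange(k + 1)
    with np.errstate(divide="ignore"):
        return stats.poisson.logpmf(y[None, :], lam[:, None])


def _trunc_logw0(lam, k: int):
    """Log weights j*ln(lam) - ln j! on {0..k}: the Poisson log pmf with
    the common -lam term dropped.  Dropping it removes the catastrophic
    cancellation between pmf and normalizer at extreme rates; it cancels in
    every normalized quantity.  Requires lam > 0."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    j = np.arange(k + 1)
    return np.log(lam)[:, None] * j[None, :] - special.gammaln(j + 1.0)[None, :]


def _trunc_poisson_w(lam, k: int):
    """Normalized weights of Poisson(lam) truncated to {0..k}."""
    lw = _trunc_logw0(lam, k)
    w = np.exp(lw - lw.max(axis=1, keepdims=True))
    return w / w.sum(axis=1, keepdims=True)


def log_trunc_poisson_pmf(y, lam, k: int):
    """log P(Y=y | Y <= k) for Y ~ Poisson(lam), stable for any lam > 0."""
    y = np.atleast_1d(np.asarray(y))
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    lw = _trunc_logw0(lam, k)
    lse = special.logsumexp(lw, axis=1)
    return y * np.log(lam) - special.gammaln(y + 1.0) - lse


def poisson_logcdf(k: int, lam):
    """log P(Poisson(lam) <= k) by logsumexp over {0..k}.

    Unlike the direct log of the cdf this stays finite (≈ logpmf at k) when
    the cdf underflows, which the truncated likelihood needs far from the
    optimum.  lam = 0 gives 0.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    out = np.zeros_like(lam)
    pos = lam > 0
    if np.any(pos):
        out[pos] = special.logsumexp(_trunc_poisson_logw(lam[pos], k), axis=1)
    return out if out.size > 1 else float(out[0])


def trunc_poisson_mean(lam, k: int):
    """E[Y | Y <= k] for Y ~ Poisson(lam), by direct summation; vectorized.

    lam = 0 is allowed (point mass at 0, mean 0).
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    out = np.zeros_like(lam)
    pos = lam > 0
    if np.any(pos):
        w = _trunc_poisson_w(lam[pos], k)
        out[pos] = w @ np.arange(k + 1)
    return out if out.size > 1 else float(out[0])


def trunc_poisson_var(lam, k: int):
    """Var[Y | Y <= k] for Y ~ Poisson(lam), by direct summation; vectorized."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    out = np.zeros_like(lam)
    pos = lam > 0
    if np.any(pos):
        w = _trunc_poisson_w(lam[pos], k)
        y = np.arange(k + 1)
        m1 = w @ y
        m2 = w @ (y * y)
        out[pos] = m2 - m1 * m1
    return out if out.size > 1 else float(out[0])


def trunc_moments(rates: RatePair, y1: int, bounds: TruncationBounds) -> MomentSet:
    """Truncated moments by direct finite summation (the defining route).

    ``mean1``/``var1`` are moments of Y1 truncated at k1; ``cond_mean2`` /
    ``cond_var2`` are moments of Y2 | Y1=y1 truncated at k2.
    """
    y1 = int(_check_count(y1, "y1"))
    m1 = trunc_poisson_mean(rates.lambda1, bounds.k1)
    v1 = trunc_poisson_var(rates.lambda1, bounds.k1)
    lam2 = rates.lambda2 * y1
    m2 = trunc_poisson_mean(lam2, bounds.k2)
    v2 = trunc_poisson_var(lam2, bounds.k2)
    return MomentSet(mean1=float(m1), var1=float(v1),
                     cond_mean2=float(m2), cond_var2=float(v2))


def trunc_mean_incgamma(lam: float, k: int) -> float:
    """Truncated Poisson mean via the incomplete-gamma identity (cross-check).

    E[Y | Y <= k] = lam * Gamma(k, lam) * k / Gamma(k+1, lam)
                  = lam * Q(k, lam) / Q(k+1, lam),

    with Q the regularized upper incomplete gamma function, i.e. the ratio of
    Poisson cdfs at k-1 and k.  Defined for k >= 1; returns 0 for k = 0.
    """
    if k == 0:
        return 0.0
    return float(lam * special.gammaincc(k, lam) / special.gammaincc(k + 1, lam))


def marginal_pmf_y2(y2: int, rates: RatePair, tol: float = 1e-14) -> float:
    """P(Y2 = y2) under the untruncated model, by summing over y1.

    Internal validation utility (the marginal of Y2 is an infinite series);
    the series is truncated adaptively far beyond the effective support.
    """
    y2 = int(_check_count(y2, "y2"))
    # generous upper limit for the y1 sum
    hi = int(rates.lambda1 + 12 * np.sqrt(rates.lambda1) + y2 / max(rates.lambda2, 1e-2) + 30)
    y1 = np.arange(hi + 1)
    p = np.exp(log_joint_pmf(y1, np.full_like(y1, y2), rates))
    return float(p.sum())


def _trunc_poisson_rvs(lam, k: int, rng: np.random.Generator):
    """Inverse-cdf draws from Poisson(lam) truncated to {0..k}; lam array."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    cdf = np.cumsum(_trunc_poisson_w(lam, k), axis=1)
    u = rng.random(lam.shape[0])
    return (u[:, None] > cdf).sum(axis=1)


def sample(lambda1, lambda2=None, bounds: TruncationBounds | None = None,
           seed=None, rng: np.random.Generator | None = None):
    """Draw (Y1, Y2) pairs, one per subject, from the (truncated) model.

    Parameters
    ----------
    lambda1, lambda2
        Per-subject rates (scalars broadcast); alternatively a sequence of
        :class:`RatePair` may be passed as ``lambda1``.
    bounds
        Right-truncation bounds, or None for the untruncated model.
    seed, rng
        Seed for a fresh generator, or an existing generator.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if lambda2 is None and np.iterable(lambda1):
        pairs = list(lambda1)
        lambda1 = np.array([p.lambda1 for p in pairs])
        lambda2 = np.array([p.lambda2 for p in pairs])
    lambda1, lambda2 = np.broadcast_arrays(
        np.asarray(lambda1, dtype=float), np.asarray(lambda2, dtype=float)
    )
    lambda1 = np.atleast_1d(lambda1)
    lambda2 = np.atleast_1d(lambda2)
    if np.any(lambda1 <= 0) or np.any(lambda2 <= 0):
        raise ValueError("all rates must be positive")
    if bounds is None:
        y1 = rng.poisson(lambda1)
        y2 = rng.poisson(lambda2 * y1)
    else:
        y1 = _trunc_poisson_rvs(lambda1, bounds.k1, rng)
        y2 = np.zeros_like(y1)
        pos = y1 > 0
        if np.any(pos):
            y2[pos] = _trunc_poisson_rvs(lambda2[pos] * y1[pos], bounds.k2, rng)
    return y1.astype(np.int64), y2.astype(np.int64)
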