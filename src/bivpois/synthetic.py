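"""Synthetic covariate-dependent bivariate count data.

Generates datasets with the statistical structure the regression model
assumes — Y1 Poisson with log-linear rate, Y2 conditionally Poisson with
rate proportional to Y1 — plus controlled departures (overdispersed
conditional draws, a conditional mean unrelated to Y1) for power studies,
and optional right truncation.  Every draw is reproducible from the config
seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .distributions import TruncationBounds, _trunc_poisson_rvs
from .regression import BivariateCountData

__all__ = [
    "CovariateSpec",
    "SyntheticConfig",
    "generate",
    "scenario_suite",
    "write_dataset",
]


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate column: law is bernoulli(p), uniform(a, b) or
    normal(mu, sigma); ``standardize`` centers/scales the draws to mean 0,
    unit variance before the coefficients apply (for age-like columns, to
    keep linear predictors tame); the raw column is what gets written out.
    """

    name: str
    law: str
    params: tuple
    standardize: bool = False

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.law == "bernoulli":
            (p,) = self.params
            return rng.binomial(1, p, size=n).astype(float)
        if self.law == "uniform":
            a, b = self.params
            return rng.uniform(a, b, size=n)
        if self.law == "normal":
            mu, sigma = self.params
            return rng.normal(mu, sigma, size=n)
        raise ValueError(f"unknown covariate law {self.law!r}")

    def moments(self) -> tuple[float, float]:
        """Population mean and sd of the raw draw (for standardization)."""
        if self.law == "bernoulli":
            (p,) = self.params
            return p, float(np.sqrt(p * (1 - p)))
        if self.law == "uniform":
            a, b = self.params
            return (a + b) / 2.0, (b - a) / np.sqrt(12.0)
        mu, sigma = self.params
        return mu, sigma


@dataclass(frozen=True)
class SyntheticConfig:
    """Complete recipe for one synthetic dataset.

    ``beta1``/``beta2`` include the leading intercept and apply to the
    (possibly standardized) design.  ``dispersion_mode`` is "poisson" or
    ("negbin", vmr): the conditional draws become gamma-mixed Poisson with
    the same mean and variance vmr x mean.  ``mechanism`` is "conditional"
    (the model's own generative story) or "independent_y2", where for rows
    with y1 > 0 the conditional mean is exp(x'beta2) irrespective of y1
    (rows with y1 = 0 keep y2 = 0 so the dataset stays representable).
    """

    n: int
    beta1: tuple
    beta2: tuple
    covariates: tuple
    bounds: TruncationBounds | None = None
    dispersion_mode: tuple | str = "poisson"
    mechanism: str = "conditional"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        k = len(self.covariates) + 1
        if len(self.beta1) != k or len(self.beta2) != k:
            raise ValueError("coefficient length must be #covariates + 1")
        if self.mechanism not in ("conditional", "independent_y2"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


def _negbin_mixed_poisson(mu, vmr: float, rng: np.random.Generator):
    """Gamma-mixed Poisson draws with mean mu and variance vmr * mu."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    shape = mu[pos] / (vmr - 1.0)
    g = rng.gamma(shape, 1.0 / shape)
    out[pos] = rng.poisson(mu[pos] * g)
    return out


def generate(config: SyntheticConfig, n: int | None = None,
             seed: int | None = None) -> tuple[BivariateCountData, dict]:
    """Draw a dataset per the config; returns (data, truth record).

    ``n``/``seed`` override the config values without mutating it.  The
    truth record carries the coefficients, the standardization constants
    actually applied, and everything needed to regenerate the data.
    """
    if n is not None or seed is not None:
        config = replace(config, n=n or config.n,
                         seed=config.seed if seed is None else seed)
    rng = np.random.default_rng(config.seed)
    n = config.n
    cols, raw = [], []
    design = [np.ones(n)]
    standardization = {}
    for cov in config.covariates:
        x = cov.draw(n, rng)
        raw.append(x)
        cols.append(cov.name)
        if cov.standardize:
            mu, sd = cov.moments()
            standardization[cov.name] = {"center": mu, "scale": sd}
            design.append((x - mu) / sd)
        else:
            design.append(x)
    X = np.column_stack(design)
    beta1 = np.asarray(config.beta1, dtype=float)
    beta2 = np.asarray(config.beta2, dtype=float)
    eta1 = X @ beta1
    eta2 = X @ beta2
    if np.any(np.abs(eta1) > 40) or np.any(np.abs(eta2) > 40):
        raise ValueError("linear predictor overflows a double; rescale the config")
    lam1 = np.exp(eta1)
    lam2 = np.exp(eta2)

    if config.bounds is None:
        y1 = rng.poisson(lam1)
    else:
        y1 = _trunc_poisson_rvs(lam1, config.bounds.k1, rng)

    if config.mechanism == "independent_y2":
        mu2 = np.where(y1 > 0, lam2, 0.0)
    else:
        mu2 = lam2 * y1

    if config.dispersion_mode == "poisson":
        if config.bounds is None:
            y2 = rng.poisson(mu2)
        else:
            y2 = np.zeros(n, dtype=np.int64)
            pos = mu2 > 0
            if np.any(pos):
                y2[pos] = _trunc_poisson_rvs(mu2[pos], config.bounds.k2, rng)
    else:
        mode, vmr = config.dispersion_mode
        if mode != "negbin" or vmr <= 1:
            raise ValueError("dispersion_mode must be 'poisson' or ('negbin', vmr>1)")
        y2 = _negbin_mixed_poisson(mu2, vmr, rng)
        if config.bounds is not None:
            y2 = np.minimum(y2, config.bounds.k2)  # keep within support

    frame_cols = {"y1": y1, "y2": y2}
    frame_cols.update({c: v for c, v in zip(cols, raw)})
    df = pd.DataFrame(frame_cols)
    data = BivariateCountData(y1, y2, X, ["const", *cols])
    truth = {
        "beta1": beta1.tolist(),
        "beta2": beta2.tolist(),
        "columns": ["const", *cols],
        "covariates": [asdict(c) for c in config.covariates],
        "standardization": standardization,
        "bounds": None if config.bounds is None
        else {"k1": config.bounds.k1, "k2": config.bounds.k2},
        "dispersion_mode": list(config.dispersion_mode)
        if isinstance(config.dispersion_mode, tuple) else config.dispersion_mode,
        "mechanism": config.mechanism,
        "n": int(n),
        "seed": int(config.seed),
    }
    data.frame = df  # raw columns for CSV round-trips
    return data, truth


def write_dataset(data: BivariateCountData, truth: dict, csv_path, truth_path=None):
    """Write the per-subject CSV and a JSON truth sidecar."""
    frame = getattr(data, "frame", None)
    if frame is None:
        frame = pd.DataFrame({"y1": data.y1, "y2": data.y2})
        for j, name in enumerate(data.columns):
            if name != "const":
                frame[name] = data.X[:, j]
    frame.to_csv(csv_path, index=False)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2)


_Z = (CovariateSpec("z", "normal", (0.0, 1.0)),)

_HRS_COVARIATES = (
    CovariateSpec("gender", "bernoulli", (0.40,)),
    CovariateSpec("age", "uniform", (50.0, 90.0), standardize=True),
    CovariateSpec("race", "bernoulli", (0.10,)),
    CovariateSpec("veteran", "bernoulli", (0.25,)),
)


def scenario_suite() -> dict[str, SyntheticConfig]:
    """Named study conditions used across the test and calibration suites.

    - well_specified: the model's own generative story, one normal covariate.
    - truncated: same, right-truncated at (k1=8, k2=10) — light truncation.
    - truncated_tight: right truncation at (k1=5, k2=6) with rates high
      enough that 5-10% of the untruncated mass lies beyond each bound, so
      the truncated and untruncated variants are genuinely distinguishable
      (the condition for the model-selection studies).
    - overdispersed: conditional variance twice the conditional mean.
    - independent: conditional mean of Y2 unrelated to Y1 (misspecification).
    - hrs_shaped: four covariates shaped like the health-survey application
      (binary gender/race/veteran, uniform age 50-90), intercepts set so
      E(Y1) is near 2.6 and E(Y2) near 0.77.
    """
    return {
        "well_specified": SyntheticConfig(
            n=1000, beta1=(0.5, -0.3), beta2=(-0.2, 0.4), covariates=_Z),
        "truncated": SyntheticConfig(
            n=1000, beta1=(0.5, -0.3), beta2=(-0.2, 0.4), covariates=_Z,
            bounds=TruncationBounds(8, 10)),
        "truncated_tight": SyntheticConfig(
            n=1000, beta1=(1.0, 0.2), beta2=(-0.2, 0.2), covariates=_Z,
            bounds=TruncationBounds(5, 6)),
        "overdispersed": SyntheticConfig(
            n=1000, beta1=(0.5, -0.3), beta2=(-0.2, 0.4), covariates=_Z,
            dispersion_mode=("negbin", 2.0)),
        "independent": SyntheticConfig(
            n=1000, beta1=(0.5, -0.3), beta2=(-0.5, 0.2), covariates=_Z,
            mechanism="independent_y2"),
        "hrs_shaped": SyntheticConfig(
            n=5568,
            beta1=(0.953, -0.055, 0.160, 0.007, 0.048),
            beta2=(-1.374, 0.345, -0.260, -0.174, 0.093),
            covariates=_HRS_COVARIATES),
    }
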