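"""CSV ingestion, analysis orchestration and JSON report serialization.

`run_analysis` wires the whole pipeline together — fit, dispersion,
adjusted inference, T1, T2, likelihood-ratio test against the
intercept-only model, and (when both variants are requested) the Vuong
comparison — into a single serializable RunReport shaped like the summary
tables practitioners publish for these models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import (TestResult, adjusted_inference, dispersion,
                          dispersion_T2, gof_T1, vuong)
from .distributions import TruncationBounds
from .regression import (BivariateCountData, FitResult, ModelSpec, fit,
                         fit_intercept_only, lr_test)

__all__ = ["read_data", "run_analysis", "RunReport"]


def read_data(path, y1_col: str = "y1", y2_col: str = "y2",
              covariate_cols: list[str] | None = None) -> BivariateCountData:
    """Read a per-subject CSV (header row required) into validated data.

    Counts must be non-negative integers; missing values anywhere are an
    error — nothing is dropped silently.
    """
    df = pd.read_csv(path)
    data = BivariateCountData.from_frame(df, y1_col, y2_col, covariate_cols)
    data.frame = df
    return data


def _fit_table(fit_result: FitResult) -> dict:
    t = {"names": fit_result.names, "beta1": fit_result.beta1.tolist(),
         "beta2": fit_result.beta2.tolist()}
    for attr in ("se", "zvalues", "pvalues", "se_adj", "z_adj", "p_adj"):
        v = getattr(fit_result, attr)
        if v is not None:
            q = fit_result.q
            t[attr] = {"marginal": np.asarray(v)[:q].tolist(),
                       "conditional": np.asarray(v)[q:].tolist()}
    return t


def _test_dict(t: TestResult) -> dict:
    return {"statistic": t.statistic, "df": t.df, "p_value": t.p_value,
            "warnings": list(t.warnings)}


@dataclass
class RunReport:
    """Serializable record of one full analysis."""

    spec: dict
    summary: dict
    table: dict
    loglik: float
    aic: float
    bic: float
    dispersion: dict
    t1: dict
    t2: dict
    lrt: dict | None = None
    vuong_test: dict | None = None
    secondary_table: dict | None = None
    seed: int | None = None
    version: str = __version__

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "RunReport":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            try:
                d = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    d = json.load(fh)
        return cls(**d)

    def render(self) -> str:
        """Plain-text table: estimate, se, z, p and adjusted columns."""
        lines = [f"bivpois {self.version}  variant={self.spec['variant']}"]
        lines.append(f"n = {self.summary['n']}   logLik = {self.loglik:.2f}   "
                     f"AIC = {self.aic:.2f}   BIC = {self.bic:.2f}")
        t = self.table
        for part in ("marginal", "conditional"):
            beta = t["beta1"] if part == "marginal" else t["beta2"]
            lines.append(f"-- {part} part --")
            hdr = f"{'term':>12} {'estimate':>10}"
            if "se" in t:
                hdr += f" {'se':>9} {'z':>8} {'p':>7}"
            if "se_adj" in t:
                hdr += f" {'se_adj':>9} {'p_adj':>7}"
            lines.append(hdr)
            for j, name in enumerate(t["names"]):
                row = f"{name:>12} {beta[j]:>10.4f}"
                if "se" in t:
                    row += (f" {t['se'][part][j]:>9.4f} {t['zvalues'][part][j]:>8.3f}"
                            f" {t['pvalues'][part][j]:>7.3f}")
                if "se_adj" in t:
                    row += f" {t['se_adj'][part][j]:>9.4f} {t['p_adj'][part][j]:>7.3f}"
                lines.append(row)
        d = self.dispersion
        lines.append(f"dispersion: phi1 = {d['phi1']:.3f}  phi2 = {d['phi2']:.3f}")
        lines.append(f"T1 = {self.t1['statistic']:.2f} (df {self.t1['df']}, "
                     f"p = {self.t1['p_value']:.3f})")
        lines.append(f"T2 = {self.t2['statistic']:.2f} (df {self.t2['df']}, "
                     f"p = {self.t2['p_value']:.3f})")
        if self.lrt is not None:
            lines.append(f"LRT = {self.lrt['statistic']:.2f} (df {self.lrt['df']}, "
                         f"p = {self.lrt['p_value']:.3f})")
        if self.vuong_test is not None:
            v = self.vuong_test
            lines.append(f"Vuong (truncated vs untruncated): V = {v['adjusted_V']:.2f} "
                         f"(p = {v['p_value']:.3f}), favors {v['favored']}")
        return "\n".join(lines)


def run_analysis(data: BivariateCountData, spec: ModelSpec | None = None,
                 compare_variants: bool = False, denominator: str = "per_observation",
                 seed: int | None = None) -> RunReport:
    """Fit, test and (optionally) compare; assemble a RunReport.

    With ``compare_variants`` the other variant is also fitted and the
    adjusted Vuong statistic reported as truncated (numerator) versus
    untruncated (denominator).  The LRT against the intercept-only model is
    included whenever the spec has covariates.
    """
    spec = spec or ModelSpec()
    main = fit(data, spec)
    disp = dispersion(data, main)
    adjusted_inference(main, disp)
    t1 = gof_T1(data, main, denominator=denominator)
    t2 = dispersion_T2(data, main, disp, denominator=denominator)

    lrt = None
    if main.q > 1:
        reduced = fit_intercept_only(data, main.spec, compute_se=False)
        lr = lr_test(main, reduced)
        lrt = {"statistic": lr.statistic, "df": lr.df, "p_value": lr.p_value}

    vg = None
    secondary_table = None
    if compare_variants:
        if main.spec.variant == "untruncated":
            other_spec = ModelSpec("right_truncated",
                                   TruncationBounds(int(data.y1.max()),
                                                    int(data.y2.max())))
        else:
            other_spec = ModelSpec()
        other = fit(data, other_spec)
        trunc_fit = main if main.spec.variant == "right_truncated" else other
        untrunc_fit = other if trunc_fit is main else main
        v = vuong(data, trunc_fit, untrunc_fit)
        vg = {"raw_V": v.raw_V, "adjusted_V": v.adjusted_V, "p_value": v.p_value,
              "favored": {"model_f": "right_truncated",
                          "model_g": "untruncated",
                          "neither": "neither"}[v.favored],
              "degenerate": v.degenerate}
        secondary_table = _fit_table(other)

    spec_echo = {"variant": main.spec.variant,
                 "bounds": None if main.spec.bounds is None
                 else {"k1": main.spec.bounds.k1, "k2": main.spec.bounds.k2},
                 "covariates": data.columns[1:],
                 "denominator": denominator}
    return RunReport(
        spec=spec_echo,
        summary=data.describe(),
        table=_fit_table(main),
        loglik=float(main.loglik), aic=float(main.aic), bic=float(main.bic),
        dispersion={"phi1": disp.phi1, "phi2": disp.phi2,
                    "variant": disp.variant, "n_used1": disp.n_used1,
                    "n_used2": disp.n_used2, "p_used": disp.p_used},
        t1=_test_dict(t1), t2=_test_dict(t2), lrt=lrt, vuong_test=vg,
        secondary_table=secondary_table, seed=seed)
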