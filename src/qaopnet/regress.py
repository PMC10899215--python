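"""Dose–response and response–response characterization.

Linear mixed models with a donor-specific random intercept quantify how
strongly each node tracks dose within an exposure repetition and how
strongly node pairs track each other with all exposures pooled; a cubic
polynomial provides a fixed-effects alternative for the pairwise case.
Fits are by maximum likelihood and fold changes are log-transformed
before regression (R-squared quantities are invariant to the log base;
the natural log matches the replicate model's scale).

The reported conditional R² follows the Nakagawa–Schielzeth variance
partition: (σ²_fixed + σ²_donor) / (σ²_fixed + σ²_donor + σ²_resid),
where σ²_fixed is the population variance of the fixed-effect predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ConvergenceError, SingularError
from .resample import ReplicateDataset


@dataclass
class LMMFit:
    """Coefficients, variance components and R² of one fitted model."""

    kind: str
    response: str
    predictor: str
    coefficients: dict[str, float]
    sigma_n2: float  # donor random-intercept variance (0 for fixed models)
    sigma_e2: float  # residual variance
    r2: float        # conditional R² (LMM) or training R² (polynomial)
    n_obs: int = 0
    extra: dict = field(default_factory=dict)


def _prep(data: ReplicateDataset | pd.DataFrame) -> pd.DataFrame:
    if isinstance(data, ReplicateDataset):
        df = data.means.copy()
    else:
        df = data.copy()
    df["y"] = np.log(df["fold_change"])
    return df


def _conditional_r2(fixed_pred: np.ndarray, sigma_n2: float, sigma_e2: float) -> float:
    var_f = float(np.var(fixed_pred))
    tot = var_f + sigma_n2 + sigma_e2
    return float(var_f + sigma_n2) / tot if tot > 0 else 1.0


def _fit_mixed(df: pd.DataFrame, formula: str) -> tuple:
    if df["y"].std(ddof=0) == 0:
        raise SingularError("response has zero variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["donor"])
        try:
            fit = model.fit(reml=False, method=["lbfgs", "powell"])
            sigma_n2 = float(np.asarray(fit.cov_re)[0, 0])
            sigma_e2 = float(fit.scale)
            fixed = np.asarray(fit.predict(df))
            return fit, fixed, sigma_n2, sigma_e2
        except (np.linalg.LinAlgError, ValueError):
            # the donor-intercept variance collapsed to the zero boundary;
            # the boundary ML solution is the fixed-effects OLS fit
            try:
                fit = smf.ols(formula, df).fit()
            except (np.linalg.LinAlgError, ValueError) as err:
                raise ConvergenceError(str(err)) from err
    fixed = np.asarray(fit.predict(df))
    sigma_e2 = float(fit.mse_resid) if fit.df_resid > 0 else 0.0
    return fit, fixed, 0.0, sigma_e2


def fit_dose_lmm(
    data: ReplicateDataset | pd.DataFrame,
    node: str,
    exposure: int,
) -> LMMFit:
    """Dose–response LMM for one node at one exposure repetition.

    x = β₀ + β₁·dose + donor intercept + ε on log replicate means.
    """
    df = _prep(data)
    df = df[(df.node == node) & (df.exposure == exposure)]
    if df.dose.nunique() < 2 or df.donor.nunique() < 2:
        raise SingularError("need >=2 doses and >=2 donors")
    fit, fixed, sigma_n2, sigma_e2 = _fit_mixed(df, "y ~ dose")
    coefs = {k: float(v) for k, v in getattr(fit, "fe_params", getattr(fit, "params", {})).items()}
    return LMMFit(
        kind="dose-lmm",
        response=node,
        predictor="dose",
        coefficients=coefs,
        sigma_n2=sigma_n2,
        sigma_e2=sigma_e2,
        r2=_conditional_r2(fixed, sigma_n2, sigma_e2),
        n_obs=len(df),
    )


def _pair_frame(data, node: str, node2: str) -> pd.DataFrame:
    df = _prep(data)
    a = df[df.node == node].set_index(["donor", "exposure", "dose"])["y"]
    b = df[df.node == node2].set_index(["donor", "exposure", "dose"])["y"]
    out = pd.DataFrame({"y": a, "x": b}).dropna().reset_index()
    return out


def fit_rr_lmm(
    data: ReplicateDataset | pd.DataFrame,
    node: str,
    node2: str,
) -> LMMFit:
    """Response–response LMM (all exposures pooled, donor random intercept)."""
    df = _pair_frame(data, node, node2)
    if node == node2:
        return LMMFit("rr-lmm", node, node2, {"Intercept": 0.0, "x": 1.0},
                      0.0, 0.0, 1.0, len(df))
    fit, fixed, sigma_n2, sigma_e2 = _fit_mixed(df, "y ~ x")
    coefs = {k: float(v) for k, v in getattr(fit, "fe_params", getattr(fit, "params", {})).items()}
    return LMMFit(
        kind="rr-lmm",
        response=node,
        predictor=node2,
        coefficients=coefs,
        sigma_n2=sigma_n2,
        sigma_e2=sigma_e2,
        r2=_conditional_r2(fixed, sigma_n2, sigma_e2),
        n_obs=len(df),
    )


def fit_rr_poly(
    data: ReplicateDataset | pd.DataFrame,
    node: str,
    node2: str,
) -> LMMFit:
    """Cubic polynomial response–response fit, training R² by the usual formula."""
    df = _pair_frame(data, node, node2)
    X = np.column_stack([np.ones(len(df)), df.x, df.x**2, df.x**3])
    y = df.y.to_numpy(float)
    if np.var(y) == 0:
        raise SingularError("response has zero variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.OLS(y, X).fit()
    coefs = dict(zip(["Intercept", "x", "x2", "x3"], map(float, res.params)))
    return LMMFit(
        kind="rr-poly",
        response=node,
        predictor=node2,
        coefficients=coefs,
        sigma_n2=0.0,
        sigma_e2=float(res.mse_resid) if res.df_resid > 0 else 0.0,
        r2=float(res.rsquared),
        n_obs=len(df),
    )


def r2_table(
    data: ReplicateDataset,
    mode: str,
    nodes: list[str] | None = None,
    exposures: list[int] | None = None,
) -> pd.DataFrame:
    """Batch R² computation.

    mode 'dose': one row per (node, exposure); modes 'rr-lmm'/'rr-poly':
    one row per ordered node pair with exposures pooled (both directions
    recorded — the mixed model is not direction-symmetric).
    """
    nodes = nodes if nodes is not None else data.graph.biology_nodes
    rows = []
    if mode == "dose":
        exposures = exposures or sorted(data.means.exposure.unique())
        for v in nodes:
            for e in exposures:
                f = fit_dose_lmm(data, v, e)
                rows.append({"node": v, "exposure": e, "r2": f.r2,
                             **{f"b_{k}": c for k, c in f.coefficients.items()}})
    elif mode in ("rr-lmm", "rr-poly"):
        fitter = fit_rr_lmm if mode == "rr-lmm" else fit_rr_poly
        for v in nodes:
            for v2 in nodes:
                if v == v2:
                    continue
                f = fitter(data, v, v2)
                rows.append({"node": v, "node2": v2, "r2": f.r2})
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows)
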