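"""Energy-sink equations and residual feed-efficiency traits.

The central objects are three residual traits of a lactating dairy cow:

* **RFI** (residual feed intake): the residual of DMI after a linear mixed
  model with fixed effects of parity, NESec, MBW and BEC and a random
  intercept for treatment nested within experiment.  Negative RFI = the cow
  ate less than predicted = more efficient.
* **residual MFE / MPE**: the analogous residuals of milk fat / protein
  gross efficiency (g of component per kg DMI), whose models additionally
  include DMI as a fixed effect.  Here *larger* residuals mean more
  efficient.

Supporting closed forms: NESec (net energy secreted in milk, Mcal/d),
metabolic body weight (BW^0.75) and body energy change (Mcal/d) from BCS
and daily BW change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

log = logging.getLogger(__name__)

RESPONSES = ("DMI", "MFE", "MPE")

#: residual-trait name per modelled response
RESIDUAL_NAME = {"DMI": "RFI", "MFE": "residual_MFE", "MPE": "residual_MPE"}


def nesec(fat_kg, protein_kg, lactose_kg):
    """Net energy secreted in milk (Mcal/d) from component yields (kg/d)."""
    fat_kg, protein_kg, lactose_kg = (np.asarray(x, float)
                                      for x in (fat_kg, protein_kg, lactose_kg))
    if (fat_kg < 0).any() or (protein_kg < 0).any() or (lactose_kg < 0).any():
        raise ValueError("component yields must be non-negative")
    out = 9.29 * fat_kg + 5.47 * protein_kg + 3.95 * lactose_kg
    return out if out.ndim else float(out)


def metabolic_bw(bw_kg):
    """Metabolic body weight, BW^0.75 (kg^0.75)."""
    bw_kg = np.asarray(bw_kg, float)
    if (bw_kg <= 0).any():
        raise ValueError("body weight must be positive")
    out = bw_kg ** 0.75
    return out if out.ndim else float(out)


def bec(bcs, bw_change):
    """Body energy change (Mcal/d): [2.88 + 1.036 x BCS] x BW change (kg/d)."""
    bcs, bw_change = np.asarray(bcs, float), np.asarray(bw_change, float)
    if ((bcs < 1) | (bcs > 5)).any():
        raise ValueError("BCS must lie in [1, 5]")
    out = (2.88 + 1.036 * bcs) * bw_change
    return out if out.ndim else float(out)


def gross_efficiency(component_g, dmi_kg):
    """Gross efficiency: g of milk component per kg of DMI."""
    component_g, dmi_kg = np.asarray(component_g, float), np.asarray(dmi_kg, float)
    if (dmi_kg <= 0).any():
        raise ValueError("DMI must be positive")
    out = component_g / dmi_kg
    return out if out.ndim else float(out)


@dataclass
class LMMFit:
    """A fitted residual-trait model and its variance bookkeeping."""

    response: str
    fixed_effects: pd.Series          # estimates, incl. Intercept
    fixed_se: pd.Series
    group_effects: pd.Series          # predicted random intercepts per cohort
    residual_variance: float
    random_intercept_variance: float
    residuals: pd.Series              # conditional residuals per cow
    marginal_residuals: pd.Series     # response - fixed part only
    total_r2: float                   # conditional: 1 - RSS_cond / TSS
    marginal_r2: float
    predictor_r2: dict = field(default_factory=dict)
    design_columns: tuple = ()


def _design(cows: pd.DataFrame, response: str) -> tuple[pd.DataFrame, pd.Series]:
    """Fixed-effect design matrix and response vector for a residual model."""
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}")
    required = {"parity", "fat_kg", "protein_kg", "lactose_kg", "BW", "BCS",
                "BW_change", "DMI"}
    missing = required - set(cows.columns)
    if missing:
        raise ValueError(f"cow table lacks columns: {sorted(missing)}")
    X = pd.DataFrame(index=cows.index)
    # primiparous is the reference level
    X["parity"] = (cows["parity"] == "multiparous").astype(float)
    if response != "DMI":
        X["DMI"] = cows["DMI"].astype(float)
    X["NESec"] = nesec(cows["fat_kg"], cows["protein_kg"], cows["lactose_kg"])
    X["MBW"] = metabolic_bw(cows["BW"])
    X["BEC"] = bec(cows["BCS"], cows["BW_change"])
    if response == "DMI":
        y = cows["DMI"].astype(float)
    elif response == "MFE":
        y = pd.Series(gross_efficiency(cows["fat_kg"] * 1000.0, cows["DMI"]),
                      index=cows.index)
    else:
        y = pd.Series(gross_efficiency(cows["protein_kg"] * 1000.0, cows["DMI"]),
                      index=cows.index)
    if X.isna().values.any() or y.isna().any():
        raise ValueError("missing covariate or response values")
    return X, y


def _ols_residual_fit(X: pd.DataFrame, y: pd.Series, response: str,
                      groups: pd.Series) -> LMMFit:
    Xc = sm.add_constant(X, prepend=True).rename(columns={"const": "Intercept"})
    res = sm.OLS(y, Xc).fit()
    resid = y - res.fittedvalues
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - float((resid ** 2).sum()) / tss
    return LMMFit(
        response=response,
        fixed_effects=res.params, fixed_se=res.bse,
        group_effects=pd.Series(0.0, index=sorted(groups.unique())),
        residual_variance=float(res.scale), random_intercept_variance=0.0,
        residuals=resid, marginal_residuals=resid,
        total_r2=r2, marginal_r2=r2,
        design_columns=tuple(X.columns))


def fit_residual_model(cows: pd.DataFrame, response: str = "DMI",
                       reml: bool = True,
                       force_zero_variance: bool = False) -> LMMFit:
    """Fit the residual-trait model and return conditional residuals.

    The model has the response's fixed effects plus one random intercept per
    treatment-within-experiment cohort, fitted by REML.  Conditional
    residuals (response minus fixed part minus predicted cohort effect) are
    the residual trait: RFI for DMI, residual MFE/MPE otherwise.

    ``force_zero_variance`` pins the random-intercept variance at zero, in
    which case the fit reduces exactly to OLS on the fixed part.
    """
    X, y = _design(cows, response)
    groups = (cows["experiment_id"].astype(str) + "/"
              + cows["treatment_id"].astype(str))
    n_groups = groups.nunique()
    if force_zero_variance or n_groups < 2:
        if n_groups < 2:
            log.warning("fewer than 2 cohort groups: falling back to OLS")
        return _ols_residual_fit(X, y, response, groups)
    Xc = sm.add_constant(X, prepend=True).rename(columns={"const": "Intercept"})
    if np.linalg.matrix_rank(Xc.values) < Xc.shape[1]:
        raise ValueError("singular fixed-effect design")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance warnings
        model = MixedLM(y, Xc, groups=groups)
        res = model.fit(reml=reml)
    if float(np.asarray(res.cov_re).ravel()[0]) < 1e-10:
        # variance at the boundary: the fit degenerates to OLS exactly
        log.info("random-intercept variance at zero for %s: using the OLS "
                 "limit", response)
        return _ols_residual_fit(X, y, response, groups)
    fe = res.fe_params
    fixed_part = pd.Series(Xc.values @ fe.values, index=y.index)
    ranef = pd.Series({g: float(np.asarray(v).ravel()[0])
                       for g, v in res.random_effects.items()})
    group_part = groups.map(ranef)
    resid = y - fixed_part - group_part
    marginal = y - fixed_part
    tss = float(((y - y.mean()) ** 2).sum())
    total_r2 = 1 - float((resid ** 2).sum()) / tss
    marginal_r2 = 1 - float((marginal ** 2).sum()) / tss
    return LMMFit(
        response=response,
        fixed_effects=fe, fixed_se=res.bse_fe,
        group_effects=ranef,
        residual_variance=float(res.scale),
        random_intercept_variance=float(np.asarray(res.cov_re).ravel()[0]),
        residuals=resid, marginal_residuals=marginal,
        total_r2=total_r2, marginal_r2=marginal_r2,
        design_columns=tuple(X.columns))


def variance_decomposition(cows: pd.DataFrame, response: str = "DMI",
                           fit: LMMFit | None = None) -> dict:
    """Drop-one R-squared per predictor plus the cohort share.

    For each fixed effect k, R2_k = (RSS_without_k - RSS_full) / TSS with the
    model refitted without that predictor (random structure retained); the
    cohort share drops the random intercept instead.  The parts need not sum
    to the total R-squared.
    """
    if fit is None:
        fit = fit_residual_model(cows, response)
    X, y = _design(cows, response)
    tss = float(((y - y.mean()) ** 2).sum())
    rss_full = float((fit.residuals ** 2).sum())
    out = {}
    for col in fit.design_columns:
        sub = cows.copy()
        reduced = _drop_column_fit(sub, X.drop(columns=[col]), y, cows)
        out[col] = (float((reduced ** 2).sum()) - rss_full) / tss
    no_random = _ols_residual_fit(X, y, response,
                                  cows["treatment_id"].astype(str))
    out["cohort"] = (float((no_random.residuals ** 2).sum()) - rss_full) / tss
    out["total_r2"] = fit.total_r2
    return out


def _drop_column_fit(sub, X_reduced, y, cows) -> pd.Series:
    """Conditional residuals of the model refit without one predictor."""
    if np.linalg.matrix_rank(sm.add_constant(X_reduced, prepend=True).values) \
            < X_reduced.shape[1] + 1:
        raise ValueError("singular reduced design")
    groups = (cows["experiment_id"].astype(str) + "/"
              + cows["treatment_id"].astype(str))
    Xc = sm.add_constant(X_reduced, prepend=True)
    if groups.nunique() < 2:
        res = sm.OLS(y, Xc).fit()
        return y - res.fittedvalues
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = MixedLM(y, Xc, groups=groups).fit(reml=True)
    if float(np.asarray(res.cov_re).ravel()[0]) < 1e-10:
        ols = sm.OLS(y, Xc).fit()
        return y - ols.fittedvalues
    fixed_part = pd.Series(Xc.values @ res.fe_params.values, index=y.index)
    ranef = pd.Series({g: float(np.asarray(v).ravel()[0])
                       for g, v in res.random_effects.items()})
    return y - fixed_part - groups.map(ranef)


def compute_traits(cows: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """All derived traits per cow plus the three model reports.

    Returns a per-cow table with NESec, MBW, BEC, MFE, MPE, RFI,
    residual_MFE and residual_MPE, and a dict of model summaries mirroring
    the mixed-model results table layout.
    """
    traits = pd.DataFrame(index=cows.index)
    traits["cow_id"] = cows["cow_id"] if "cow_id" in cows else cows.index
    traits["DMI"] = cows["DMI"].astype(float)
    traits["NESec"] = nesec(cows["fat_kg"], cows["protein_kg"],
                            cows["lactose_kg"])
    traits["MBW"] = metabolic_bw(cows["BW"])
    traits["BEC"] = bec(cows["BCS"], cows["BW_change"])
    traits["MFE"] = gross_efficiency(cows["fat_kg"] * 1000.0, cows["DMI"])
    traits["MPE"] = gross_efficiency(cows["protein_kg"] * 1000.0, cows["DMI"])
    reports = {}
    for response in RESPONSES:
        fit = fit_residual_model(cows, response)
        decomp = variance_decomposition(cows, response, fit)
        traits[RESIDUAL_NAME[response]] = fit.residuals
        reports[response] = {
            "estimates": fit.fixed_effects.to_dict(),
            "se": fit.fixed_se.to_dict(),
            "predictor_r2": {k: v for k, v in decomp.items()
                             if k not in ("total_r2",)},
            "total_r2": fit.total_r2,
            "marginal_r2": fit.marginal_r2,
            "residual_share": 1 - fit.total_r2,
            "random_intercept_variance": fit.random_intercept_variance,
            "residual_variance": fit.residual_variance,
        }
    return traits, reports
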