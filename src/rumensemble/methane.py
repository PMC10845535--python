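"""Equation-based enteric methane metrics and selection comparisons.

Daily methane production per cow is predicted from intake and diet
composition:

    CH4 (g/d) = (1.23*DMI - 1.45*FA% + 0.120*NDF%) / 0.05565

with DMI in kg/d and dietary fatty acids / NDF as % of DM.  Derived
metrics: yield (g per kg DMI), intensity (g per Mcal NESec) and CH4
corrected for gross feed efficiency (GFE, g milk per g DMI).  A
hypothetical selection analysis contrasts the 50 most vs 50 least
efficient cows under different ranking criteria (measured RFI, predicted
RFI, genomic PTA, residual MFE/MPE) and reports group means, SEM, Welch
p-values and percent reductions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import extreme_groups

log = logging.getLogger(__name__)

#: variables compared between selection groups
REPORT_VARIABLES = ("DMI", "NESec", "MBW", "BEC", "ch4_g_d", "ch4_yield",
                    "ch4_intensity", "ch4_per_gfe")


def ch4_production(dmi, fatty_acid_pct, ndf_pct):
    """Predicted methane production (g/d per cow)."""
    dmi = np.asarray(dmi, float)
    fa = np.asarray(fatty_acid_pct, float)
    ndf = np.asarray(ndf_pct, float)
    if (dmi < 0).any():
        raise ValueError("DMI must be non-negative")
    for name, v in (("fatty acid", fa), ("NDF", ndf)):
        if ((v < 0) | (v > 100)).any():
            raise ValueError(f"{name} percentage out of [0, 100]")
    out = (1.23 * dmi - 1.45 * fa + 0.120 * ndf) / 0.05565
    if (out < 0).any():
        log.warning("negative predicted CH4: inputs outside the equation's "
                    "validated domain")
    return out if out.ndim else float(out)


def ch4_yield(ch4_gd, dmi):
    """Methane yield, g per kg DMI."""
    dmi = np.asarray(dmi, float)
    if (dmi <= 0).any():
        raise ValueError("DMI must be positive")
    out = np.asarray(ch4_gd, float) / dmi
    return out if out.ndim else float(out)


def ch4_intensity(ch4_gd, nesec):
    """Methane intensity, g per Mcal of net energy secreted in milk."""
    nesec = np.asarray(nesec, float)
    if (nesec <= 0).any():
        raise ValueError("NESec must be positive")
    out = np.asarray(ch4_gd, float) / nesec
    return out if out.ndim else float(out)


def gfe(milk_g, dmi_g):
    """Gross feed efficiency: g of milk per g of DMI."""
    dmi_g = np.asarray(dmi_g, float)
    if (dmi_g <= 0).any():
        raise ValueError("DMI must be positive")
    out = np.asarray(milk_g, float) / dmi_g
    return out if out.ndim else float(out)


def ch4_per_gfe(ch4_gd, milk_g, dmi_g):
    """CH4 production corrected for gross feed efficiency: CH4 / GFE."""
    g = gfe(milk_g, dmi_g)
    if (np.asarray(g) <= 0).any():
        raise ValueError("GFE must be positive")
    out = np.asarray(ch4_gd, float) / g
    return out if out.ndim else float(out)


def ch4_combined_correction(ch4_gd, dmi_kg, nesec):
    """Alternative correction combining yield and intensity multiplicatively.

    Returns CH4_yield * CH4_intensity (g^2 per kg DMI per Mcal NESec); the
    operational definition of a GFE-corrected CH4 is not settled, so both
    this and :func:`ch4_per_gfe` are offered.
    """
    out = np.asarray(ch4_yield(ch4_gd, dmi_kg)) * np.asarray(
        ch4_intensity(ch4_gd, nesec))
    return out if out.ndim else float(out)


@dataclass
class MethaneReport:
    """Group comparison for one ranking criterion."""

    criterion: str
    table: pd.DataFrame   # per variable: means, SEM, diff, pct_reduction, p


def add_methane_columns(cows: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Per-cow methane metrics appended to the trait table."""
    out = traits.copy()
    ch4 = ch4_production(cows["DMI"], cows["diet_fatty_acid_pct"],
                         cows["diet_ndf_pct"])
    out["ch4_g_d"] = ch4
    out["ch4_yield"] = ch4_yield(ch4, cows["DMI"])
    out["ch4_intensity"] = ch4_intensity(ch4, out["NESec"])
    out["ch4_per_gfe"] = ch4_per_gfe(ch4, cows["milk_kg"] * 1000.0,
                                     cows["DMI"] * 1000.0)
    return out


def selection_comparison(data: pd.DataFrame, criterion: str,
                         n_each: int = 50,
                         higher_is_efficient: bool = False,
                         variables=REPORT_VARIABLES) -> MethaneReport:
    """Most- vs least-efficient group contrast under one ranking criterion.

    ``data`` holds the criterion column plus the report variables per cow.
    Reports group means, SEM, the least-minus-most difference, the percent
    reduction relative to the least-efficient group, and Welch p-values.
    """
    if criterion not in data.columns:
        raise ValueError(f"criterion column {criterion!r} missing")
    groups = extreme_groups(data[criterion], n_each=n_each,
                            higher_is_efficient=higher_is_efficient)
    most = data.loc[groups == "most_efficient"]
    least = data.loc[groups == "least_efficient"]
    rows = {}
    for var in variables:
        a = least[var].to_numpy(float)
        b = most[var].to_numpy(float)
        diff = a.mean() - b.mean()
        if np.allclose(a.std(), 0) and np.allclose(b.std(), 0):
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows[var] = {
            "mean_most": b.mean(), "sem_most": stats.sem(b) if len(b) > 1 else 0.0,
            "mean_least": a.mean(), "sem_least": stats.sem(a) if len(a) > 1 else 0.0,
            "difference": diff,
            "pct_reduction": 100.0 * diff / a.mean() if a.mean() > 0 else np.nan,
            "pvalue": p,
            "significant": p <= 0.05,
        }
    return MethaneReport(criterion=criterion,
                         table=pd.DataFrame.from_dict(rows, orient="index"))


def _terciles(x: pd.Series) -> np.ndarray:
    """0 = efficient (lowest), 1 = average, 2 = not efficient; stable ties."""
    n = len(x)
    order = np.argsort(x.to_numpy(), kind="stable")
    cat = np.empty(n, int)
    sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    start = 0
    for label, size in enumerate(sizes):
        cat[order[start:start + size]] = label
        start += size
    return cat


CATEGORIES = ("efficient", "average", "not_efficient")


def interplay_crosstab(phenotypic_rfi: pd.Series,
                       microbiome_pred_rfi: pd.Series,
                       pta_rfi: pd.Series) -> dict:
    """Tercile cross-tabulation of measured vs predicted efficiency.

    Each score is cut into terciles (lower = efficient).  Returns the
    3x3x3 count cube (phenotype x microbiome x PTA) and both marginal 3x3
    tables against the phenotype.
    """
    idx = phenotypic_rfi.index
    if not (microbiome_pred_rfi.index.equals(idx) and pta_rfi.index.equals(idx)):
        raise ValueError("inputs must be aligned on the same cows")
    ph = _terciles(phenotypic_rfi)
    mb = _terciles(microbiome_pred_rfi)
    pt = _terciles(pta_rfi)
    cube = np.zeros((3, 3, 3), int)
    np.add.at(cube, (ph, mb, pt), 1)
    return {
        "cube": cube,
        "phenotype_x_microbiome": cube.sum(axis=2),
        "phenotype_x_pta": cube.sum(axis=1),
        "categories": CATEGORIES,
    }
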