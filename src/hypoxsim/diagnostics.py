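"""Hypoxia metrics, oxygen-budget decomposition, stratification index, and
trend statistics.

Hypoxia uses the conventional threshold of 2 mg O2/L (62.5 mmol/m3 at a
molar mass of 32 g/mol).  The hypoxic volume of a column ensemble is the
sum over columns of (hypoxic layer thickness x column area); the oxygen
budget splits the inventory change of the "bottom water" (below each
column's reference interface, by default the deepest third) into diffusive
supply, photosynthetic production, respiration/remineralization,
nitrification, oyster respiration and sediment oxygen demand, and asserts
that the ledger closes.  Trend significance is ordinary least squares with
a two-sided t-test on the slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .bgc import MG_L_TO_MMOL_M3
from .column import ColumnGrid

__all__ = ["HypoxiaMetrics", "OxygenBudget", "TrendFit", "hypoxic_threshold",
           "hypoxic_volume", "oxygen_budget", "summer_mean_n2", "linear_trend",
           "SUMMER_MONTHS"]

#: June-September, the summer-mean window for annual statistics.
SUMMER_MONTHS = (6, 7, 8, 9)


def hypoxic_threshold(mg_per_l: float = 2.0) -> float:
    """Threshold in mmol O2/m3 for a threshold given in mg/L."""
    return mg_per_l * MG_L_TO_MMOL_M3


@dataclass
class HypoxiaMetrics:
    """Ensemble hypoxia summary for one snapshot or record set."""

    threshold_mg_l: float
    threshold_mmol_m3: float
    thickness_m: Dict[int, float]        # per column index
    volume_km3: float
    frequency: float                     # fraction of records hypoxic

    def __post_init__(self):
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must be in [0,1]")


def hypoxic_volume(o2_profiles: Sequence[np.ndarray],
                   grids: Sequence[ColumnGrid],
                   threshold_mg_l: float = 2.0) -> HypoxiaMetrics:
    """Hypoxic thickness per column and total ensemble hypoxic volume.

    ``o2_profiles[i]`` is the oxygen profile (mmol/m3) on ``grids[i]``;
    profiles may be 2-D (time, layer), in which case the thickness is the
    per-record mean and the frequency counts records with any hypoxic
    layer.
    """
    thr = hypoxic_threshold(threshold_mg_l)
    thickness: Dict[int, float] = {}
    volume = 0.0
    n_rec = 0
    n_hyp = 0
    for i, (o2, grid) in enumerate(zip(o2_profiles, grids)):
        o2 = np.atleast_2d(np.asarray(o2, dtype=float))
        if o2.shape[1] != grid.nz:
            raise ValueError("profile length does not match grid")
        th_rec = np.array([float(np.sum(grid.dz[row < thr])) for row in o2])
        thickness[i] = float(th_rec.mean())
        volume += thickness[i] * grid.area_m2 / 1e9     # m*m2 -> km3
        n_rec += th_rec.size
        n_hyp += int(np.sum(th_rec > 0))
    freq = n_hyp / n_rec if n_rec else 0.0
    return HypoxiaMetrics(threshold_mg_l=threshold_mg_l, threshold_mmol_m3=thr,
                          thickness_m=thickness, volume_km3=volume,
                          frequency=freq)


@dataclass
class OxygenBudget:
    """Time-integrated bottom-water oxygen budget, mmol O2/m2 over the
    integration window.  ``residual`` is the closure defect."""

    dinv: float
    diffusive_supply: float
    production: float
    respiration: float
    nitrification: float
    oyster_respiration: float
    sod: float
    clamp: float
    residual: float

    def consumption_total(self) -> float:
        return (self.respiration + self.nitrification
                + self.oyster_respiration + self.sod)


def oxygen_budget(ledger: pd.DataFrame, rtol: float = 1e-8,
                  check: bool = True) -> OxygenBudget:
    """Integrate a column's step ledger into a bottom-water oxygen budget.

    The closure identity
    ``dinv = diffusion + production - respiration - nitrification -
    oyster - SOD + clamp``
    is asserted to ``rtol`` (relative to total turnover) when ``check``.
    """
    need = ["o2_dinv_below", "o2_diff_in", "o2_prod_below", "o2_resp_below",
            "o2_nitr_below", "o2_oyster_below", "o2_sod", "o2_clamp_below"]
    for c in need:
        if c not in ledger.columns:
            raise KeyError(f"ledger missing term {c!r}")
    s = ledger[need].sum()
    budget = OxygenBudget(
        dinv=s["o2_dinv_below"],
        diffusive_supply=s["o2_diff_in"],
        production=s["o2_prod_below"],
        respiration=s["o2_resp_below"],
        nitrification=s["o2_nitr_below"],
        oyster_respiration=s["o2_oyster_below"],
        sod=s["o2_sod"],
        clamp=s["o2_clamp_below"],
        residual=0.0,
    )
    rhs = (budget.diffusive_supply + budget.production - budget.respiration
           - budget.nitrification - budget.oyster_respiration - budget.sod
           + budget.clamp)
    budget.residual = budget.dinv - rhs
    if check:
        scale = max(abs(budget.dinv), abs(budget.diffusive_supply),
                    budget.consumption_total(), 1e-12)
        if abs(budget.residual) > rtol * scale:
            raise AssertionError(
                f"oxygen budget does not close: residual {budget.residual:.3e} "
                f"vs scale {scale:.3e}")
    return budget


def summer_mean_n2(records: pd.DataFrame, value: str = "n2_mean",
                   months: Tuple[int, ...] = SUMMER_MONTHS) -> pd.Series:
    """Volume-weighted regional summer-mean stratification index per year.

    ``records`` is a tidy frame with columns ``year``, ``month``,
    ``area_km2``, ``depth_m`` and the stratification value; weighting is by
    column volume (area x depth).
    """
    df = records[records["month"].isin(months)].copy()
    if df.empty:
        return pd.Series(dtype=float)
    df["w"] = df["area_km2"] * df["depth_m"]
    out = df.groupby("year").apply(
        lambda g: np.average(g[value], weights=g["w"]), include_groups=False)
    out.name = value
    return out


@dataclass
class TrendFit:
    """OLS linear trend of an annual series."""

    slope: float
    intercept: float
    pvalue: float
    significant: bool
    degenerate: bool = False


def linear_trend(series: pd.Series | np.ndarray,
                 alpha: float = 0.05) -> TrendFit:
    """Least-squares trend with a two-sided t-test on the slope.

    A constant series has an undefined p-value and is flagged degenerate
    rather than reported significant.
    """
    if isinstance(series, pd.Series):
        x = np.asarray(series.index, dtype=float)
        y = np.asarray(series.values, dtype=float)
    else:
        y = np.asarray(series, dtype=float)
        x = np.arange(y.size, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 points for a trend")
    if np.ptp(y) == 0.0:
        return TrendFit(slope=0.0, intercept=float(y[0]), pvalue=np.nan,
                        significant=False, degenerate=True)
    fit = stats.linregress(x, y)
    p = float(fit.pvalue)
    return TrendFit(slope=float(fit.slope), intercept=float(fit.intercept),
                    pvalue=p, significant=bool(p < alpha))
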