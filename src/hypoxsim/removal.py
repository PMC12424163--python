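"""Oyster nitrogen-removal accounting, national scaling, and valuation.

Converts the farm-scale nitrogen ledger (mol N/d assimilated, returned,
net removed) into an areal removal rate (g N/m2/yr), scales it to a
national farming area (t N/yr), expresses it as a fraction of an annual
riverine nitrogen load, and prices it at a nutrient-credit market rate.
Nitrogen molar mass 14.0 g/mol and 365-day years throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import pandas as pd
import yaml

__all__ = ["RemovalBudget", "ValuationParams", "areal_rate", "scale_national",
           "load_fraction", "valuation", "removal_report"]

N_MOLAR_MASS = 14.0
DAYS_PER_YEAR = 365.0


@dataclass
class RemovalBudget:
    """Farm-scale nitrogen removal ledger (daily-rate units)."""

    assimilated: float          # mol N/d
    returned: float             # mol N/d (excretion + mortality)
    farm_area_km2: float

    def __post_init__(self):
        if self.farm_area_km2 <= 0:
            raise ValueError("farm area must be > 0")
        if self.net < -1e-9 * max(self.assimilated, 1.0):
            raise ValueError("net removal is negative beyond tolerance")

    @property
    def net(self) -> float:
        """Net removal, mol N/d."""
        return self.assimilated - self.returned

    @property
    def areal_rate(self) -> float:
        """g N/m2/yr."""
        return areal_rate(self.net, self.farm_area_km2)


@dataclass
class ValuationParams:
    """National-scale context for the removal chain."""

    national_area_km2: float = 2349.0       # oyster farming area (2022)
    riverine_load_t_yr: float = 3.1e6       # annual riverine N input
    price_usd_per_kg: float = 32.3          # nitrogen credit price

    def __post_init__(self):
        if min(self.national_area_km2, self.riverine_load_t_yr,
               self.price_usd_per_kg) <= 0:
            raise ValueError("valuation parameters must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "ValuationParams":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def areal_rate(net_mol_per_day: float, area_km2: float) -> float:
    """Annual areal nitrogen removal, g N/m2/yr, from a daily molar rate."""
    if area_km2 <= 0:
        raise ZeroDivisionError("farm area must be > 0")
    return net_mol_per_day * N_MOLAR_MASS * DAYS_PER_YEAR / (area_km2 * 1e6)


def scale_national(rate_g_m2_yr: float, national_area_km2: float) -> float:
    """Removal when the areal rate is applied to a national area, t N/yr."""
    return rate_g_m2_yr * national_area_km2 * 1e6 / 1e6  # g->t and km2->m2 cancel


def load_fraction(removal_t_yr: float, load_t_yr: float) -> float:
    """Removal as a percentage of an annual riverine nitrogen load."""
    if load_t_yr <= 0:
        raise ZeroDivisionError("riverine load must be > 0")
    return 100.0 * removal_t_yr / load_t_yr


def valuation(removal_t_yr: float, price_usd_per_kg: float) -> float:
    """Monetary value of the removal, USD/yr."""
    return removal_t_yr * 1000.0 * price_usd_per_kg


def removal_report(budget: RemovalBudget,
                   params: Optional[ValuationParams] = None) -> pd.DataFrame:
    """One-page report: the full chain from the farm ledger to valuation."""
    params = params or ValuationParams()
    rate = budget.areal_rate
    national = scale_national(rate, params.national_area_km2)
    rows = [
        ("assimilated PON", budget.assimilated, "mol N/d"),
        ("returned (excretion + mortality)", budget.returned, "mol N/d"),
        ("net removal", budget.net, "mol N/d"),
        ("farm area", budget.farm_area_km2, "km2"),
        ("areal removal rate", rate, "g N/m2/yr"),
        ("national farming area", params.national_area_km2, "km2"),
        ("national removal", national, "t N/yr"),
        ("riverine N load", params.riverine_load_t_yr, "t N/yr"),
        ("fraction of riverine load", load_fraction(national, params.riverine_load_t_yr), "%"),
        ("nitrogen price", params.price_usd_per_kg, "USD/kg-N"),
        ("annual value", valuation(national, params.price_usd_per_kg), "USD/yr"),
    ]
    return pd.DataFrame(rows, columns=["quantity", "value", "units"])
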