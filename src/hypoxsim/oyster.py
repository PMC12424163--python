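"""Filter-feeding oyster module: filtration, metabolism, biodeposition.

A farm of fixed-biomass oysters (no growth, no harvest) occupies the upper
layers of a column.  Each step the population clears water at a rate set by
a maximum clearance rate modulated by piecewise-linear temperature,
salinity and oxygen limitation factors (filtration shuts down entirely in
severe hypoxia).  Filtered particulate organic nitrogen (phytoplankton,
zooplankton, small/large detritus and terrestrial POM) is split into

* assimilated N  — of which a fraction is catabolized and excreted as
  ammonium (with the matching phosphate at the fixed N:P ratio and an
  oxygen cost through a respiratory quotient), and
* biodeposits    — pseudofeces rejected before ingestion plus feces, routed
  to a dedicated oyster-detritus pool that sinks and remineralizes in the
  water column and sediment.

Basal metabolism (Q10 temperature scaling) catabolizes stock nitrogen;
mortality returns stock nitrogen to the detritus pool.  Because biomass is
held fixed, assimilated nitrogen not returned by excretion or mortality is
booked as *removed* from the system — the accounting behind the nitrogen
bioextraction budget.

Nitrogen closes exactly per step:
``filtered = assimilated + biodeposited`` per food type, and
``assimilated = net removal + excreted + mortality-returned``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import yaml

__all__ = ["OysterParams", "OysterPopulation", "FiltrationResult",
           "filtration", "metabolism", "biodeposition_and_mortality",
           "net_removal", "oyster_step", "FOOD_TYPES"]

#: Particulate pools the oysters filter (in kernel tracer names).
FOOD_TYPES = ("phy", "zoo", "sdet", "ldet", "pom_t")

#: grams of nitrogen per mole.
N_MOLAR_MASS = 14.0


def ramp(x, points: Tuple[float, float, float, float]):
    """Trapezoidal piecewise-linear limitation in [0, 1].

    ``points = (x0, x1, x2, x3)``: 0 below x0, linear rise to 1 at x1,
    flat 1 to x2, linear fall to 0 at x3.
    """
    x0, x1, x2, x3 = points
    x = np.asarray(x, dtype=float)
    up = np.clip((x - x0) / (x1 - x0), 0.0, 1.0) if x1 > x0 else (x >= x0) * 1.0
    down = np.clip((x3 - x) / (x3 - x2), 0.0, 1.0) if x3 > x2 else (x <= x2) * 1.0
    return np.minimum(up, down)


@dataclass
class OysterParams:
    """Physiological constants for a reference 1 g dry-weight oyster."""

    clearance_max: float = 0.08          # m3 per individual per day
    temp_points: Tuple[float, float, float, float] = (5.0, 18.0, 30.0, 38.0)
    sal_points: Tuple[float, float, float, float] = (2.0, 10.0, 35.0, 40.0)
    o2_shutdown: float = 31.25           # mmol/m3 (~1 mg/L): filtration ceases
    o2_full: float = 93.75               # mmol/m3 (~3 mg/L): no limitation above

    # assimilation efficiency per food type (fraction of ingested)
    assim_eff: Dict[str, float] = field(default_factory=lambda: {
        "phy": 0.8, "zoo": 0.8, "sdet": 0.5, "ldet": 0.5, "pom_t": 0.3})
    pseudofeces_frac: float = 0.05       # rejected before ingestion

    excretion_frac: float = 0.5          # fraction of assimilated N catabolized -> NH4
    basal_rate: float = 0.001            # /d at t_ref, applied to stock N
    q10: float = 2.0
    t_ref: float = 24.0                  # degC
    resp_cost: float = 0.1               # extra mol O2-equivalent N per mol assimilated
    mortality_rate: float = 0.001        # /d of stock N -> oyster detritus
    o2_per_n: float = 6.625              # respiratory quotient, mol O2 per mol N

    w_oydet: float = 5.0                 # oyster-detritus sinking, m/d
    r_oydet: float = 0.2                 # water-column remineralization, /d

    max_depletion_per_step: float = 0.9  # cap on fractional food removal per step

    def validate(self) -> None:
        for k, v in self.assim_eff.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"assimilation efficiency for {k} outside [0,1]")
        if not 0.0 <= self.pseudofeces_frac <= 1.0:
            raise ValueError("pseudofeces_frac outside [0,1]")
        if not 0.0 <= self.excretion_frac <= 1.0:
            raise ValueError("excretion_frac outside [0,1]")
        if self.clearance_max < 0 or self.mortality_rate < 0 or self.basal_rate < 0:
            raise ValueError("rates must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "OysterParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "temp_points" in data:
            data["temp_points"] = tuple(data["temp_points"])
        if "sal_points" in data:
            data["sal_points"] = tuple(data["sal_points"])
        return cls(**data)


@dataclass
class OysterPopulation:
    """Farm geometry and stocking.

    The biomass of 1 g dry weight per individual is held fixed for the
    whole run; there is no growth or harvest.
    """

    area_km2: float = 100.0
    density: float = 100.0               # individuals per m2
    biomass_g_dw: float = 1.0            # per individual, fixed
    n_content: float = 0.07              # g N per g dry weight
    occupied_layers: Sequence[int] = (0, 1, 2)
    params: OysterParams = field(default_factory=OysterParams)

    def __post_init__(self):
        if self.density < 0 or self.area_km2 < 0:
            raise ValueError("density and farm area must be >= 0")

    @property
    def area_m2(self) -> float:
        return self.area_km2 * 1e6

    @property
    def n_individuals(self) -> float:
        return self.density * self.area_m2

    @property
    def stock_n_mol(self) -> float:
        """Standing-stock nitrogen of the whole farm, mol N."""
        return self.n_individuals * self.biomass_g_dw * self.n_content / N_MOLAR_MASS


@dataclass
class FiltrationResult:
    """Per-step farm-scale nitrogen and oxygen ledger (mol/d units)."""

    filtered: Dict[str, float]           # mol N/d per food type
    assimilated: Dict[str, float]
    biodeposited: Dict[str, float]       # pseudofeces + feces
    specific_rate: float = 0.0           # /d removal rate applied in occupied layers
    excreted_nh4: float = 0.0            # mol N/d
    excreted_po4: float = 0.0            # mol P/d
    respiration_o2: float = 0.0          # mol O2/d
    mortality_return: float = 0.0        # mol N/d to oyster detritus

    @property
    def filtered_total(self) -> float:
        return sum(self.filtered.values())

    @property
    def assimilated_total(self) -> float:
        return sum(self.assimilated.values())

    @property
    def biodeposited_total(self) -> float:
        return sum(self.biodeposited.values())


def filtration(T: float, S: float, o2: float, food: Mapping[str, float],
               pop: OysterPopulation, occupied_volume_m3: float,
               dt: float = 1.0) -> FiltrationResult:
    """Filter-feeding fluxes for one step.

    ``food`` maps food-type name to its mean concentration (mmol N/m3) in
    the occupied layers.  The per-type filtered flux is
    ``clearance * f_T * f_S * f_O2 * concentration * density * area``;
    the same specific removal rate (volume cleared / occupied volume)
    applies to every food type, capped so no more than
    ``max_depletion_per_step`` of the standing stock is removed in ``dt``.
    """
    p = pop.params
    if min(T, S, o2) < 0 or any(c < 0 for c in food.values()):
        raise ValueError("negative physical input to filtration")
    f_t = float(ramp(T, p.temp_points))
    f_s = float(ramp(S, p.sal_points))
    if o2 <= p.o2_shutdown:
        f_o2 = 0.0
    else:
        f_o2 = float(np.clip((o2 - p.o2_shutdown) / (p.o2_full - p.o2_shutdown),
                             0.0, 1.0))
    cleared = p.clearance_max * f_t * f_s * f_o2 * pop.n_individuals  # m3/d
    rate = cleared / occupied_volume_m3 if occupied_volume_m3 > 0 else 0.0
    # cap: fraction removed in dt is rate*dt; scale demand proportionally
    if rate * dt > p.max_depletion_per_step:
        rate = p.max_depletion_per_step / dt

    filtered, assim, biodep = {}, {}, {}
    for ft in FOOD_TYPES:
        conc = float(food.get(ft, 0.0))
        f_mol = rate * conc * occupied_volume_m3 / 1000.0  # mmol -> mol N/d
        ingested = f_mol * (1.0 - p.pseudofeces_frac)
        a = ingested * p.assim_eff[ft]
        filtered[ft] = f_mol
        assim[ft] = a
        biodep[ft] = f_mol - a
    return FiltrationResult(filtered=filtered, assimilated=assim,
                            biodeposited=biodep, specific_rate=rate)


def metabolism(assimilated: float, T: float, pop: OysterPopulation,
               r_np: float = 16.0, o2_throttle: float = 1.0
               ) -> Tuple[float, float, float]:
    """Excretion and respiration of the farm.

    Returns ``(excreted NH4 mol N/d, excreted PO4 mol P/d, O2 sink mol/d)``.
    The oxygen sink is ``(basal(T) * stock + cost * assimilated) * RQ`` with
    Q10 temperature scaling of the basal rate; excreted nitrogen is the
    catabolized fraction of assimilated N plus the basal term, with
    phosphate following at the fixed N:P ratio.  ``o2_throttle`` in [0, 1]
    depresses the basal term under severe hypoxia (N and O2 scaled
    together, preserving the respiratory stoichiometry).
    """
    if assimilated < 0:
        raise ValueError("assimilated N must be >= 0")
    p = pop.params
    basal = (p.basal_rate * p.q10 ** ((T - p.t_ref) / 10.0)
             * pop.stock_n_mol * o2_throttle)
    metabolized = basal + p.excretion_frac * assimilated
    o2_sink = (basal + p.resp_cost * assimilated) * p.o2_per_n
    return metabolized, metabolized / r_np, o2_sink


def biodeposition_and_mortality(result: FiltrationResult,
                                pop: OysterPopulation) -> float:
    """Source of oyster-derived detritus, mol N/d.

    Biodeposits (pseudofeces + feces) plus the mortality return of stock
    nitrogen.  The pool subsequently sinks at its own speed and
    remineralizes in the water column and, on deposition, in the sediment;
    that fate is handled by the column and sediment modules.
    """
    mort = pop.params.mortality_rate * pop.stock_n_mol
    return result.biodeposited_total + mort


def net_removal(assimilated: float, excreted_n: float,
                mortality_n: float) -> float:
    """Net nitrogen removal, mol N/d: assimilation minus all returns."""
    if min(assimilated, excreted_n, mortality_n) < 0:
        raise ValueError("budget terms must be >= 0")
    return assimilated - excreted_n - mortality_n


def oyster_step(T: float, S: float, o2: float, food: Mapping[str, float],
                pop: OysterPopulation, occupied_volume_m3: float,
                dt: float = 1.0, r_np: float = 16.0) -> FiltrationResult:
    """Complete per-step oyster ledger: filtration, metabolism, mortality."""
    res = filtration(T, S, o2, food, pop, occupied_volume_m3, dt)
    exc_n, exc_p, o2_sink = metabolism(res.assimilated_total, T, pop, r_np)
    mort = pop.params.mortality_rate * pop.stock_n_mol
    res.excreted_nh4 = exc_n
    res.excreted_po4 = exc_p
    res.respiration_o2 = o2_sink
    res.mortality_return = mort
    return res
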