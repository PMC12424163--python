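"""Management scenarios and the time-slice experiment design.

Three named scenarios drive the column ensemble:

* ``ConstantN``   — river nutrient concentrations held at their 2015
  (reference-year) levels through 2100;
* ``DecreasingN`` — concentrations decline linearly at configured
  per-species rates (floored at zero), with phosphate leveling off at a
  floor of 1 mmol/m3 from 2024 onward;
* ``Oyster``      — the DecreasingN nutrient rules plus an oyster farm
  (100 km2 at 100 individuals/m2 of fixed 1 g dry-weight oysters) in the
  designated farm column(s).

The reference-year concentrations and decline rates are configuration
values, not published quantities: they are chosen so end-of-century
DecreasingN levels are a small fraction of the 2015 levels.

Experiments use a time-slice strategy: each year only the biologically
active May 1 - September 30 window is simulated, initialized from a
seeded climatological May state produced by a burn-in run; annual summer
statistics are means over June-September.  The default projection windows
are the near-term (2016-2045) and long-term (2071-2100) 30-year blocks;
scaled-down windows are used for the standard test fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bgc import BGCParams, BGCState
from .column import ColumnGrid, ColumnModel, PhysicsParams, run_column
from .forcing import ForcingConfig, ForcingSeries, generate_forcing
from .oyster import OysterParams, OysterPopulation
from .sediment import SedimentParams
from .diagnostics import SUMMER_MONTHS

__all__ = ["ScenarioSpec", "ColumnSpec", "ExperimentResult",
           "river_concentration", "run_time_slice", "compare_scenarios",
           "default_columns", "standard_fixture_columns", "SCENARIO_NAMES"]

SCENARIO_NAMES = ("ConstantN", "DecreasingN", "Oyster")

#: Default projection windows: near-term and long-term 30-year blocks.
DEFAULT_WINDOWS = ((2016, 2045), (2071, 2100))

SEASON_START = (5, 1)      # May 1
SEASON_END = (9, 30)       # September 30
SEASON_DAYS = 153


@dataclass
class ScenarioSpec:
    """A named nutrient-trajectory rule plus oyster configuration."""

    name: str = "DecreasingN"
    # reference-year (2015) river concentrations, mmol/m3
    ref_conc: Dict[str, float] = field(default_factory=lambda: {
        "no3": 100.0, "nh4": 8.0, "po4": 2.0, "don": 20.0, "pon": 12.0})
    # linear decline rates, mmol/m3 per year (DecreasingN / Oyster only)
    decline: Dict[str, float] = field(default_factory=lambda: {
        "no3": 1.0, "nh4": 0.08, "po4": 0.12, "don": 0.2, "pon": 0.12})
    po4_floor: float = 1.0
    po4_floor_year: int = 2024
    # oyster configuration (used only by the Oyster scenario)
    oyster_density: float = 100.0          # individuals/m2
    oyster_params: OysterParams = field(default_factory=OysterParams)
    farm_occupied_depth_m: float = 4.0
    windows: Tuple[Tuple[int, int], ...] = DEFAULT_WINDOWS
    seed: int = 0

    def __post_init__(self):
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}")
        if any(v < 0 for v in self.decline.values()):
            raise ValueError("decline rates must be >= 0")
        if self.po4_floor < 0:
            raise ValueError("po4 floor must be >= 0")

    @property
    def has_oysters(self) -> bool:
        return self.name == "Oyster" and self.oyster_density > 0

    def years(self) -> List[int]:
        out: List[int] = []
        for y0, y1 in self.windows:
            out.extend(range(y0, y1 + 1))
        return out


def river_concentration(spec: ScenarioSpec, species: str, year: int) -> float:
    """Annual river concentration level, mmol/m3 (seasonal cycle applied
    downstream by the forcing shape).

    ConstantN holds the reference-year level; DecreasingN (and the Oyster
    case, which inherits its nutrient rules) declines linearly, floored at
    zero, with phosphate leveling off at the configured floor from the
    floor year onward.
    """
    if species not in spec.ref_conc:
        raise KeyError(f"unknown river species {species!r}")
    if not 2015 <= year <= 2100:
        raise ValueError(f"year {year} outside the projection range 2015-2100")
    ref = spec.ref_conc[species]
    if spec.name == "ConstantN":
        return ref
    rate = spec.decline.get(species, 0.0)
    c = max(ref - (year - 2015) * rate, 0.0)
    if species == "po4" and year >= spec.po4_floor_year:
        c = max(c, min(spec.po4_floor, ref))
    return c


@dataclass
class ColumnSpec:
    """One member of the regional hypsography."""

    depth_m: float
    area_km2: float
    farm: bool = False
    nz: int = 30


def default_columns(nz: int = 30) -> List[ColumnSpec]:
    """Default hypsography: a shallow western farm-footprint column plus
    progressively deeper shelf columns (region total 3000 km2)."""
    return [
        ColumnSpec(depth_m=14.0, area_km2=100.0, farm=True, nz=nz),
        ColumnSpec(depth_m=10.0, area_km2=600.0, nz=nz),
        ColumnSpec(depth_m=18.0, area_km2=800.0, nz=nz),
        ColumnSpec(depth_m=24.0, area_km2=900.0, nz=nz),
        ColumnSpec(depth_m=30.0, area_km2=600.0, nz=nz),
    ]


def standard_fixture_columns() -> List[ColumnSpec]:
    """Reduced hypsography for the standard test fixture: four columns at
    coarser vertical resolution (the farm footprint keeps its 100 km2)."""
    return [
        ColumnSpec(depth_m=14.0, area_km2=100.0, farm=True, nz=16),
        ColumnSpec(depth_m=12.0, area_km2=900.0, nz=16),
        ColumnSpec(depth_m=20.0, area_km2=1200.0, nz=16),
        ColumnSpec(depth_m=28.0, area_km2=800.0, nz=16),
    ]


@dataclass
class ExperimentResult:
    """Per-step records and per-year summer statistics for one scenario."""

    spec: ScenarioSpec
    records: pd.DataFrame        # tidy: year, month, day, column, ledger fields
    summer: pd.DataFrame         # per-year June-September means / ensemble sums
    columns: List[ColumnSpec]

    def window_years(self, window: Tuple[int, int]) -> pd.DataFrame:
        y0, y1 = window
        return self.summer[(self.summer.index >= y0) & (self.summer.index <= y1)]

    def window_mean(self, metric: str, window: Tuple[int, int]) -> float:
        return float(self.window_years(window)[metric].mean())


def _season_forcing(series: ForcingSeries, spec: ScenarioSpec, year: int,
                    dt: float) -> List[Dict[str, float]]:
    """Per-step surface forcing dicts for one May-September season."""
    n_steps = int(round(SEASON_DAYS / dt))
    doy0 = 120.0                               # April 30 -> season starts May 1
    t_days = doy0 + dt * (np.arange(n_steps) + 0.5)
    t_years = year + t_days / 365.0
    chans = {k: series.interp_at(k, t_years)
             for k in ("irradiance", "temperature", "salinity", "wind",
                       "discharge", "river_conc_shape")}
    levels = {sp: river_concentration(spec, sp, year) for sp in spec.ref_conc}
    steps = []
    for i in range(n_steps):
        f = {k: float(v[i]) for k, v in chans.items()}
        shape = f.pop("river_conc_shape")
        for sp, lv in levels.items():
            f[f"river_{sp}"] = lv * shape
        # month number for the summer-mean bookkeeping
        f["_month"] = int(1 + np.searchsorted(
            np.cumsum([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]),
            t_days[i] % 365, side="right"))
        f["_day"] = float(t_days[i])
        steps.append(f)
    return steps


def _build_model(col: ColumnSpec, spec: ScenarioSpec, bgc: BGCParams,
                 phys: PhysicsParams, sed: SedimentParams,
                 region_area_km2: float) -> ColumnModel:
    grid = ColumnGrid.regular(col.depth_m, nz=col.nz, area_km2=col.area_km2)
    pop = None
    if spec.has_oysters and col.farm:
        occ = tuple(np.flatnonzero(
            grid.z_centers < spec.farm_occupied_depth_m).tolist()) or (0,)
        pop = OysterPopulation(area_km2=col.area_km2,
                               density=spec.oyster_density,
                               occupied_layers=occ,
                               params=spec.oyster_params)
    return ColumnModel(grid, bgc_params=replace(bgc), physics=phys,
                       sediment=sed, population=pop,
                       river_area_km2=region_area_km2)


def _burn_in_state(model: ColumnModel, steps: Sequence[Mapping[str, float]],
                   dt: float, days: float, seed: int) -> BGCState:
    """Seeded climatological May state: start from a perturbed uniform
    profile and spin up under early-season forcing."""
    rng = np.random.default_rng(seed)
    state = BGCState.uniform(model.grid.nz)
    for k in ("phy", "zoo", "sdet", "no3", "po4"):
        state[k] = state[k] * (1.0 + 0.05 * rng.standard_normal(model.grid.nz))
        state[k] = np.maximum(state[k], 0.0)
    n_steps = int(round(days / dt))
    for i in range(n_steps):
        model.step(state, steps[i % len(steps)], dt)
    return state


def run_time_slice(spec: ScenarioSpec, forcing: ForcingSeries,
                   columns: Optional[Sequence[ColumnSpec]] = None,
                   dt: float = 0.5,
                   bgc: Optional[BGCParams] = None,
                   phys: Optional[PhysicsParams] = None,
                   sed: Optional[SedimentParams] = None,
                   burn_in_days: float = 30.0) -> ExperimentResult:
    """Run the seeded time-slice experiment for one scenario.

    For every year in the scenario windows the May-September season is
    integrated for each ensemble column, starting from the scenario's
    climatological May state (one seeded burn-in per column, reused across
    years).  Identical ``(spec, forcing)`` give identical results.
    """
    columns = list(columns if columns is not None else default_columns())
    bgc = bgc or BGCParams()
    phys = phys or PhysicsParams()
    sed = sed or SedimentParams()
    region_area = sum(c.area_km2 for c in columns)
    years = spec.years()
    if forcing.time_years.min() > years[0] or forcing.time_years.max() < years[-1]:
        raise ValueError("forcing does not cover the scenario windows")

    frames = []
    for ci, col in enumerate(columns):
        model = _build_model(col, spec, bgc, phys, sed, region_area)
        may_steps = _season_forcing(forcing, spec, years[0], dt)
        init = _burn_in_state(model, may_steps, dt, burn_in_days,
                              seed=spec.seed * 1000 + ci)
        for year in years:
            steps = _season_forcing(forcing, spec, year, dt)
            state = init.copy()
            run = run_column(model, state, steps, dt,
                             archive_every=max(1, len(steps)))
            led = run.ledger.reset_index(drop=True)
            led["month"] = [s["_month"] for s in steps]
            led["day"] = [s["_day"] for s in steps]
            led["year"] = year
            led["column"] = ci
            led["area_km2"] = col.area_km2
            led["depth_m"] = col.depth_m
            led["farm"] = col.farm
            frames.append(led)
    records = pd.concat(frames, ignore_index=True)
    summer = _summer_table(records)
    return ExperimentResult(spec=spec, records=records, summer=summer,
                            columns=columns)


def _summer_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-year ensemble statistics (June-September means)."""
    sm = records[records["month"].isin(SUMMER_MONTHS)]
    rows = {}
    for year, g in sm.groupby("year"):
        # ensemble hypoxic volume per step, then summer mean
        per_step = g.groupby("day").apply(
            lambda s: float(np.sum(s["hypoxic_thickness"] * s["area_km2"] * 1e6))
            / 1e9, include_groups=False)
        w = g["area_km2"] * g["depth_m"]
        farm = g[g["farm"]]
        season = records[records["year"] == year]
        farm_season = season[season["farm"]]
        rows[year] = {
            "hypoxic_volume_km3": float(per_step.mean()),
            "n2_mean": float(np.average(g["n2_mean"], weights=w)),
            "phy_surf": float(np.average(g["phy_surf"], weights=g["area_km2"])),
            "o2_bottom": float(np.average(g["o2_bottom"], weights=g["area_km2"])),
            "pon_farm": float(farm["pon_integral"].mean()) if len(farm) else np.nan,
            "deposition_farm": float(farm["n_deposition"].sum()) if len(farm) else np.nan,
            # farm totals over the full simulated season, mol/d means
            "oy_assimilated": float(farm_season["oy_assimilated"].mean())
            if len(farm_season) else 0.0,
            "oy_filtered": float(farm_season["oy_filtered"].mean())
            if len(farm_season) else 0.0,
            "oy_excreted": float(farm_season["oy_excreted"].mean())
            if len(farm_season) else 0.0,
            "oy_mortality": float(farm_season["oy_mortality"].mean())
            if len(farm_season) else 0.0,
        }
        rows[year]["oy_net_removal"] = (rows[year]["oy_assimilated"]
                                        - rows[year]["oy_excreted"]
                                        - rows[year]["oy_mortality"])
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "year"
    return out


def compare_scenarios(result_a: ExperimentResult, result_b: ExperimentResult,
                      metric: str,
                      window: Tuple[int, int]) -> Dict[str, float]:
    """Percent change of scenario A relative to B over a matched window.

    Returns ``percent_change = 100 (mean_A - mean_B)/mean_B`` plus the
    25th/75th percentiles of the per-year values in each scenario.
    """
    if result_a.spec.windows != result_b.spec.windows:
        raise ValueError("scenario windows do not match")
    a = result_a.window_years(window)[metric]
    b = result_b.window_years(window)[metric]
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("mismatched or empty windows")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if mean_b == 0.0:
        raise ZeroDivisionError("reference-scenario mean is zero")
    return {
        "percent_change": 100.0 * (mean_a - mean_b) / mean_b,
        "mean_a": mean_a, "mean_b": mean_b,
        "q25_a": float(a.quantile(0.25)), "q75_a": float(a.quantile(0.75)),
        "q25_b": float(b.quantile(0.25)), "q75_b": float(b.quantile(0.75)),
    }
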