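"""Seeded synthetic multidecadal forcing for the column-ensemble simulator.

Generates monthly surface irradiance, water temperature, salinity, wind,
river discharge and river nutrient-concentration seasonal shapes as

    value(t) = trend(t) + seasonal harmonic(t) + AR(1) anomaly(t)

clipped at physical bounds.  The generator stands in for downscaled climate
and watershed-model products: a linear surface-warming trend emulating a
high-emission (SSP5-8.5-like) trajectory, a compound multidecadal increase
in river discharge, and surface salinity tied to discharge through a linear
plume map.  Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr
import yaml

__all__ = ["ForcingConfig", "ForcingSeries", "generate_forcing", "emulate_discharge_trend"]

# Order fixes the RNG stream assignment; do not reorder.
_NOISE_CHANNELS = ("temperature", "irradiance", "wind", "discharge")

#: River nutrient species the simulator tracks (mmol/m3 as N or P).
RIVER_SPECIES = ("no3", "nh4", "po4", "don", "pon", "dop")


@dataclass
class ForcingConfig:
    """Statistical controls for the synthetic forcing generator.

    Rates with "per decade" in the name are applied over ``(t - start_year)/10``
    in fractional years.  ``discharge_trend`` is compound (a fraction per
    decade), so a 0.10 trend multiplies the mean discharge by 1.1 every
    decade; the warming trend is linear in time.
    """

    start_year: int = 2015
    end_year: int = 2100
    seed: int = 0

    # temperature (surface water, deg C)
    temperature_base: float = 24.0
    warming_rate: float = 0.45          # deg C per decade, SSP5-8.5-like
    temperature_amplitude: float = 5.0  # seasonal half-range
    temperature_phase: float = 0.55     # fraction of year of the seasonal max
    temperature_noise_std: float = 0.3

    # shortwave irradiance (W/m2, daily mean at the surface)
    irradiance_base: float = 180.0
    irradiance_amplitude: float = 60.0
    irradiance_phase: float = 0.47
    irradiance_noise_std: float = 8.0

    # wind speed (m/s)
    wind_base: float = 6.0
    wind_amplitude: float = 1.5
    wind_phase: float = 0.95            # winter monsoon maximum
    wind_noise_std: float = 0.5

    # river discharge (m3/s)
    discharge_base: float = 10000.0
    discharge_trend: float = 0.03       # fraction per decade, compound
    discharge_amplitude: float = 0.75   # relative seasonal amplitude
    discharge_phase: float = 0.5        # wet-season maximum (early July)
    discharge_noise_std: float = 0.10   # relative

    # surface salinity via linear plume map (PSU)
    salinity_ocean: float = 32.0
    plume_coefficient: float = 1.2e-3   # PSU per (m3/s) of discharge

    # interannual AR(1) anomaly structure shared by all channels
    autocorrelation: float = 0.5

    # relative seasonal amplitude of river nutrient concentrations
    river_conc_amplitude: float = 0.3
    river_conc_phase: float = 0.5

    def validate(self) -> None:
        vals = asdict(self)
        for k, v in vals.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite config value: {k}={v!r}")
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")
        if self.discharge_base < 0:
            raise ValueError("discharge_base must be >= 0")
        for k in ("temperature_amplitude", "irradiance_amplitude", "wind_amplitude",
                  "discharge_amplitude", "river_conc_amplitude",
                  "temperature_noise_std", "irradiance_noise_std",
                  "wind_noise_std", "discharge_noise_std"):
            if vals[k] < 0:
                raise ValueError(f"{k} must be >= 0")
        if not 0.0 <= self.autocorrelation < 1.0:
            raise ValueError("autocorrelation must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "ForcingConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class ForcingSeries:
    """Monthly forcing wrapped around an :class:`xarray.Dataset`.

    ``data`` carries one variable per physical channel on a CF-style
    ``time`` axis plus a ``t_years`` fractional-year coordinate used for
    trend fits and interpolation.
    """

    data: xr.Dataset

    @property
    def time_years(self) -> np.ndarray:
        return self.data["t_years"].values

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name].values

    def annual_mean(self, name: str) -> pd.Series:
        da = self.data[name]
        years = da["time"].dt.year
        return da.groupby(years).mean().to_series()

    def interp_at(self, name: str, t_years) -> np.ndarray:
        """Linear interpolation of a monthly channel to arbitrary times."""
        return np.interp(np.asarray(t_years, dtype=float),
                         self.time_years, self.data[name].values)

    def to_netcdf(self, path) -> None:
        # scipy engine -> NetCDF3 classic, no extra dependency
        self.data.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "ForcingSeries":
        return cls(xr.load_dataset(path, engine="scipy"))

    def to_csv(self, path) -> None:
        self.data.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ForcingSeries":
        df = pd.read_csv(path, index_col=0, parse_dates=True)
        return cls(xr.Dataset.from_dataframe(df))


def _ar1(rng: np.random.Generator, n: int, std: float, rho: float) -> np.ndarray:
    """Stationary AR(1) anomaly with marginal standard deviation ``std``."""
    if std == 0.0:
        return np.zeros(n)
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = eps[0] * std
    c = std * np.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + c * eps[i]
    return x


def _harmonic(t_frac: np.ndarray, amplitude: float, phase: float) -> np.ndarray:
    return amplitude * np.cos(2.0 * np.pi * (t_frac - phase))


def generate_forcing(config: ForcingConfig) -> ForcingSeries:
    """Generate the full monthly forcing series from a validated config.

    Identical ``(config, seed)`` produce bitwise-identical output.  All
    physical sign constraints (irradiance, wind, discharge, salinity >= 0)
    are enforced by clipping after the anomaly is added.
    """
    config.validate()
    years = np.arange(config.start_year, config.end_year + 1)
    n = years.size * 12
    time = pd.date_range(f"{config.start_year}-01-01", periods=n, freq="MS") \
        + pd.Timedelta(days=14)
    month_frac = (np.arange(n) % 12 + 0.5) / 12.0
    t_years = np.repeat(years, 12) + month_frac
    t_dec = (t_years - config.start_year) / 10.0

    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(config.seed).spawn(len(_NOISE_CHANNELS))]
    rng = dict(zip(_NOISE_CHANNELS, streams))
    rho = config.autocorrelation

    temperature = (config.temperature_base
                   + config.warming_rate * t_dec
                   + _harmonic(month_frac, config.temperature_amplitude,
                               config.temperature_phase)
                   + _ar1(rng["temperature"], n, config.temperature_noise_std, rho))

    irradiance = np.clip(
        config.irradiance_base
        + _harmonic(month_frac, config.irradiance_amplitude, config.irradiance_phase)
        + _ar1(rng["irradiance"], n, config.irradiance_noise_std, rho), 0.0, None)

    wind = np.clip(
        config.wind_base
        + _harmonic(month_frac, config.wind_amplitude, config.wind_phase)
        + _ar1(rng["wind"], n, config.wind_noise_std, rho), 0.0, None)

    q_rel = ((1.0 + config.discharge_trend) ** t_dec
             * (1.0 + _harmonic(month_frac, config.discharge_amplitude,
                                config.discharge_phase))
             * (1.0 + _ar1(rng["discharge"], n, config.discharge_noise_std, rho)))
    discharge = np.clip(config.discharge_base * q_rel, 0.0, None)

    salinity = np.clip(
        config.salinity_ocean - config.plume_coefficient * discharge, 0.0, None)

    conc_shape = np.clip(
        1.0 + _harmonic(month_frac, config.river_conc_amplitude,
                        config.river_conc_phase), 0.0, None)

    ds = xr.Dataset(
        {
            "irradiance": ("time", irradiance, {"units": "W m-2"}),
            "temperature": ("time", temperature, {"units": "degC"}),
            "salinity": ("time", salinity, {"units": "PSU"}),
            "wind": ("time", wind, {"units": "m s-1"}),
            "discharge": ("time", discharge, {"units": "m3 s-1"}),
            "river_conc_shape": ("time", conc_shape,
                                 {"units": "1", "long_name":
                                  "dimensionless seasonal multiplier for river concentrations"}),
        },
        coords={"time": time, "t_years": ("time", t_years)},
        attrs={"seed": config.seed},
    )
    for bad in [k for k, v in ds.items() if not np.all(np.isfinite(v))]:
        raise FloatingPointError(f"non-finite values generated in {bad}")
    return ForcingSeries(ds)


def emulate_discharge_trend(config: ForcingConfig) -> ForcingSeries:
    """Forcing restricted to the river-discharge channel.

    With ``discharge_trend >= 0`` and zero noise the decadal-mean discharge
    is non-decreasing (compound growth times a fixed seasonal shape).
    """
    if config.discharge_trend < 0:
        raise ValueError("discharge_trend must be >= 0 for the rising-discharge scenario")
    series = generate_forcing(config)
    return ForcingSeries(series.data[["discharge"]])
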