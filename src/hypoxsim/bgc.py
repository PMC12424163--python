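"""Pelagic nitrogen-phosphorus-oxygen cycle: an 11-variable NPZD-type kernel.

State variables (per layer): nitrate, ammonium, phosphate, oxygen,
chlorophyll, phytoplankton, zooplankton, small and large detritus, and
river-delivered terrestrial particulate and dissolved organic matter.
A twelfth pool, oyster-derived detritus, is carried alongside so the
filter-feeder module can couple in without changing the pelagic contract;
it is identically zero when no oysters are present.

The kernel is written as a ledger of nitrogen transfers between pools
(uptake, grazing, mortality, aggregation, remineralization, nitrification),
so total nitrogen is conserved *structurally*: every flux leaves one pool
and enters another.  Phosphate and oxygen tendencies are derived from the
same ledger through fixed stoichiometry (N:P of organic matter; distinct
O2:N yields for nitrate- and ammonium-fuelled photosynthesis; an O2:N
respiration cost; 2 mol O2 per mol NH4 nitrified).  Oxygen-consuming
rates are throttled by a piecewise-linear saturation term that is exactly
one at ample oxygen — stoichiometric budgets close to round-off — and
falls linearly to zero below a low-oxygen limit so oxygen cannot be
driven negative by the biology.

Functional forms follow the conventions of the Fennel family of coastal
nitrogen-cycle models; all rate constants are package defaults recorded in
:class:`BGCParams` and exportable to YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Dict, Tuple

import numpy as np
import yaml

__all__ = [
    "N_POOLS", "ORGANIC_POOLS", "TRACERS", "BGCParams", "BGCState",
    "RateTendencies", "growth_rate", "chl_acclimation", "grazing",
    "nitrification", "aggregation", "tendencies", "oxygen_saturation_factor",
    "MG_L_TO_MMOL_M3",
]

#: All advected/diffused tracers, in canonical order.
TRACERS = ("no3", "nh4", "po4", "o2", "chl", "phy", "zoo",
           "sdet", "ldet", "pom_t", "dom_t", "oydet")

#: Nitrogen-bearing pools entering the conservation budget.
N_POOLS = ("no3", "nh4", "phy", "zoo", "sdet", "ldet", "pom_t", "dom_t", "oydet")

#: Organic-nitrogen pools (P follows these at the fixed N:P ratio).
ORGANIC_POOLS = ("phy", "zoo", "sdet", "ldet", "pom_t", "dom_t", "oydet")

#: 1 mg O2 / L = 1000/32 mmol O2 / m3  (molar mass 32 g/mol).
MG_L_TO_MMOL_M3 = 1000.0 / 32.0


@dataclass
class BGCParams:
    """Kinetic and stoichiometric constants of the pelagic model.

    Units follow the field's conventions: specific rates per day,
    concentrations mmol/m3 (mg/m3 for chlorophyll), light W/m2.
    """

    # phytoplankton growth
    mu0: float = 0.69                  # /d, growth at 0 degC
    eppley: float = 1.066              # temperature coefficient, mu_max = mu0*eppley**T
    alpha: float = 0.025               # initial slope of P-I curve, (W/m2)^-1 d^-1
    k_no3: float = 0.5                 # mmol/m3
    k_nh4: float = 0.5                 # mmol/m3
    k_po4: float = 0.06                # mmol/m3

    # grazing (Holling type III)
    g_max: float = 0.6                 # /d
    k_p: float = 1.0                   # mmol N/m3, half-saturation of the squared response
    beta: float = 0.75                 # zooplankton assimilation fraction of grazing

    # linear and quadratic loss rates (/d except where noted)
    m_phy: float = 0.072               # phytoplankton mortality -> SDet
    l_bm: float = 0.1                  # zooplankton basal metabolism -> NH4
    m_zoo2: float = 0.025              # quadratic zoo mortality, (mmol N/m3)^-1 d^-1 -> SDet
    r_sdet: float = 0.06               # small-detritus remineralization
    r_ldet: float = 0.015              # large-detritus remineralization
    r_pom: float = 0.03                # terrestrial POM remineralization
    r_dom: float = 0.01                # terrestrial DOM remineralization
    r_oydet: float = 0.2               # oyster-detritus water-column remineralization
    tau_agg: float = 0.005             # aggregation coefficient, (mmol N/m3)^-1 d^-1

    # nitrification with light inhibition
    n_max: float = 0.05                # /d, dark maximum
    i_nitr0: float = 0.0095            # W/m2, inhibition threshold
    k_nitr_i: float = 0.1              # W/m2, inhibition saturation scale

    # sinking speeds, m/d (positive downward)
    w_phy: float = 0.5
    w_sdet: float = 1.0
    w_ldet: float = 5.0
    w_pom: float = 5.0
    w_oydet: float = 5.0

    # chlorophyll acclimation, mg Chl (mmol N)^-1
    theta_max: float = 4.2
    theta_min: float = 0.2

    # stoichiometry
    r_np: float = 16.0                 # N:P of organic matter, mol/mol
    o2_per_no3_uptake: float = 8.625   # mol O2 per mol N (nitrate-fuelled)
    o2_per_nh4_uptake: float = 6.625   # mol O2 per mol N (ammonium-fuelled)
    o2_per_n_resp: float = 6.625       # respiration / remineralization cost
    o2_per_nh4_nitrif: float = 2.0     # nitrification cost

    # oxygen throttle: rates scale by min(1, O2/o2_lim), zero below 0
    o2_lim: float = 10.0               # mmol/m3

    # light attenuation
    kd_water: float = 0.15             # /m
    kd_chl: float = 0.025              # m2/mg Chl

    def validate(self) -> None:
        d = asdict(self)
        for k, v in d.items():
            if k in ("theta_min",):
                continue
            if v < 0:
                raise ValueError(f"parameter {k} must be >= 0, got {v}")
        if self.r_np <= 0 or self.o2_per_n_resp <= 0:
            raise ValueError("stoichiometric ratios must be positive")

    @classmethod
    def from_yaml(cls, path) -> "BGCParams":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


class BGCState:
    """Per-layer tracer concentrations as a mapping of named arrays.

    All arrays share the shape ``(nz,)``.  Construction validates
    non-negativity; arithmetic on states is intentionally not provided —
    the integrator owns time stepping.
    """

    __slots__ = ("data", "nz")

    def __init__(self, **tracers: np.ndarray):
        missing = set(TRACERS) - set(tracers)
        if missing:
            raise ValueError(f"missing tracers: {sorted(missing)}")
        arrs = {k: np.asarray(tracers[k], dtype=float) for k in TRACERS}
        nz = {a.shape for a in arrs.values()}
        if len(nz) != 1:
            raise ValueError("all tracers must share one shape")
        self.data: Dict[str, np.ndarray] = arrs
        self.nz = arrs["no3"].shape[0]

    @classmethod
    def uniform(cls, nz: int, **values: float) -> "BGCState":
        base = dict(no3=8.0, nh4=0.5, po4=0.6, o2=230.0, chl=1.0, phy=0.5,
                    zoo=0.1, sdet=0.5, ldet=0.2, pom_t=0.0, dom_t=0.0, oydet=0.0)
        base.update(values)
        return cls(**{k: np.full(nz, v, dtype=float) for k, v in base.items()})

    def __getitem__(self, k: str) -> np.ndarray:
        return self.data[k]

    def __setitem__(self, k: str, v) -> None:
        self.data[k] = np.asarray(v, dtype=float)

    def copy(self) -> "BGCState":
        return BGCState(**{k: v.copy() for k, v in self.data.items()})

    def total_nitrogen(self, dz: np.ndarray) -> float:
        """Column inventory of nitrogen, mmol/m2."""
        return float(sum(np.sum(self.data[p] * dz) for p in N_POOLS))

    def total_phosphorus(self, dz: np.ndarray, r_np: float = 16.0) -> float:
        """Column P inventory: phosphate plus organic N / (N:P), mmol/m2."""
        org = sum(np.sum(self.data[p] * dz) for p in ORGANIC_POOLS)
        return float(np.sum(self.data["po4"] * dz) + org / r_np)


@dataclass
class RateTendencies:
    """Per-layer tendencies (units of each tracer per day) plus the itemized
    nitrogen-flux ledger the oxygen/nitrogen budget diagnostics consume."""

    d: Dict[str, np.ndarray]
    fluxes: Dict[str, np.ndarray]          # named N transfers, mmol N/m3/d
    o2_production: np.ndarray              # mmol O2/m3/d
    o2_respiration: np.ndarray
    o2_nitrification: np.ndarray
    light: np.ndarray                      # W/m2 at layer centres


def oxygen_saturation_factor(o2, o2_lim: float):
    """Piecewise-linear throttle: 0 at O2<=0, 1 at O2>=o2_lim."""
    return np.clip(np.asarray(o2, dtype=float) / o2_lim, 0.0, 1.0)


def growth_rate(T, I, no3, nh4, po4, params: BGCParams):
    """Specific phytoplankton growth rate with its limitation breakdown.

    mu = mu_max(T) * f(I) * min(L_NO3 + L_NH4, L_PO4) with Eppley
    temperature scaling, a saturating light response
    f = alpha*I/sqrt(mu_max^2 + alpha^2 I^2), ammonium inhibition of
    nitrate uptake, and nitrogen-phosphorus colimitation through the
    minimum.  Returns a dict with ``mu`` and every factor, plus the
    realized fraction of uptake drawn from nitrate.
    """
    T, I, no3, nh4, po4 = map(lambda x: np.asarray(x, dtype=float),
                              (T, I, no3, nh4, po4))
    if np.any(no3 < 0) or np.any(nh4 < 0) or np.any(po4 < 0):
        raise ValueError("negative nutrient concentration")
    mu_max = params.mu0 * params.eppley ** T
    f_i = params.alpha * I / np.sqrt(mu_max ** 2 + (params.alpha * I) ** 2)
    l_no3 = no3 / (params.k_no3 + no3) / (1.0 + nh4 / params.k_nh4)
    l_nh4 = nh4 / (params.k_nh4 + nh4)
    l_po4 = po4 / (params.k_po4 + po4)
    l_n = l_no3 + l_nh4
    mu = mu_max * f_i * np.minimum(l_n, l_po4)
    # l_no3 <= l_n, so the ratio is bounded even for denormal-tiny l_n
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        frac_no3 = np.where(l_n > 0, l_no3 / np.where(l_n > 0, l_n, 1.0), 0.0)
    frac_no3 = np.clip(frac_no3, 0.0, 1.0)
    return {"mu": mu, "mu_max": mu_max, "f_i": f_i, "l_no3": l_no3,
            "l_nh4": l_nh4, "l_po4": l_po4, "frac_no3": frac_no3}


def chl_acclimation(phy, chl, mu, I, params: BGCParams):
    """Chlorophyll synthesis tendency under Geider-type photoacclimation.

    The fraction of photosynthesis directed to pigment is
    rho = theta_max * mu * Phy / (alpha * I * Chl), clamped to [0, 1];
    the synthesis tendency is rho * mu * Chl.  At I = 0 (or empty pools)
    the acclimation term is defined as zero.
    """
    phy, chl, mu, I = map(lambda x: np.asarray(x, dtype=float), (phy, chl, mu, I))
    denom = params.alpha * I * chl
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0,
                       params.theta_max * mu * phy / np.where(denom > 0, denom, 1.0),
                       0.0)
    rho = np.clip(rho, 0.0, 1.0)
    return rho * mu * chl


def grazing(phy, zoo, params: BGCParams):
    """Holling type III (sigmoidal) grazing flux, mmol N/m3/d."""
    phy = np.asarray(phy, dtype=float)
    zoo = np.asarray(zoo, dtype=float)
    return params.g_max * phy ** 2 / (params.k_p ** 2 + phy ** 2) * zoo


def nitrification(nh4, I, o2, params: BGCParams):
    """Light-inhibited, oxygen-throttled nitrification flux, mmol N/m3/d.

    Phi(I) = 1 - max(0, (I - I0)/(kI + I - I0)): one in the dark,
    monotonically non-increasing, tending to zero under strong light, with
    half inhibition at I = I0 + kI.
    """
    nh4, I, o2 = map(lambda x: np.asarray(x, dtype=float), (nh4, I, o2))
    excess = np.maximum(I - params.i_nitr0, 0.0)
    phi = 1.0 - excess / (params.k_nitr_i + excess)
    return params.n_max * nh4 * phi * oxygen_saturation_factor(o2, params.o2_lim)


def aggregation(phy, sdet, params: BGCParams):
    """Quadratic coagulation of phytoplankton and small detritus into large
    detritus; returns (flux_from_phy, flux_from_sdet), split in proportion
    to each pool's share so nitrogen closes exactly."""
    phy = np.asarray(phy, dtype=float)
    sdet = np.asarray(sdet, dtype=float)
    tot = phy + sdet
    flux = params.tau_agg * tot ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(tot > 0, phy / np.where(tot > 0, tot, 1.0), 0.0)
    return flux * share, flux * (1.0 - share)


def light_profile(I_surf: float, chl: np.ndarray, dz: np.ndarray,
                  params: BGCParams) -> np.ndarray:
    """Irradiance at layer centres, attenuated by water and chlorophyll
    shading accumulated from the surface."""
    kd = params.kd_water + params.kd_chl * np.maximum(chl, 0.0)
    tau_layer = kd * dz
    tau_top = np.concatenate(([0.0], np.cumsum(tau_layer)[:-1]))
    return I_surf * np.exp(-(tau_top + 0.5 * tau_layer))


def tendencies(state: BGCState, T, I_surf: float, params: BGCParams,
               dz: np.ndarray) -> RateTendencies:
    """Assemble all pelagic source/sink terms for one column.

    Nitrogen moves only through the named transfer ledger, so the summed
    tendency over the nitrogen pools is zero to round-off.  Phosphate and
    oxygen are slaved to the ledger by fixed stoichiometry.
    """
    for k, v in state.data.items():
        if np.any(~np.isfinite(v)):
            raise FloatingPointError(f"NaN/inf in state variable {k}")
    T = np.broadcast_to(np.asarray(T, dtype=float), (state.nz,))
    dz = np.asarray(dz, dtype=float)

    I = light_profile(I_surf, state["chl"], dz, params)
    g = growth_rate(T, I, state["no3"], state["nh4"], state["po4"], params)
    mu = g["mu"]
    phy, zoo, sdet = state["phy"], state["zoo"], state["sdet"]
    f_ox = oxygen_saturation_factor(state["o2"], params.o2_lim)

    uptake = mu * phy
    graz = grazing(phy, zoo, params)
    agg_phy, agg_sdet = aggregation(phy, sdet, params)

    fluxes = {
        "uptake_no3": uptake * g["frac_no3"],            # no3 -> phy
        "uptake_nh4": uptake * (1.0 - g["frac_no3"]),    # nh4 -> phy
        "graz_to_zoo": params.beta * graz,               # phy -> zoo
        "graz_egest": (1.0 - params.beta) * graz,        # phy -> sdet
        "phy_mort": params.m_phy * phy,                  # phy -> sdet
        "zoo_metab": params.l_bm * zoo * f_ox,           # zoo -> nh4
        "zoo_mort": params.m_zoo2 * zoo ** 2,            # zoo -> sdet
        "agg_phy": agg_phy,                              # phy -> ldet
        "agg_sdet": agg_sdet,                            # sdet -> ldet
        "remin_sdet": params.r_sdet * sdet * f_ox,       # sdet -> nh4
        "remin_ldet": params.r_ldet * state["ldet"] * f_ox,
        "remin_pom": params.r_pom * state["pom_t"] * f_ox,
        "remin_dom": params.r_dom * state["dom_t"] * f_ox,
        "remin_oydet": params.r_oydet * state["oydet"] * f_ox,
        "nitrif": nitrification(state["nh4"], I, state["o2"], params),
    }
    routes = _FLUX_ROUTES

    d = {k: np.zeros(state.nz) for k in TRACERS}
    for name, arr in fluxes.items():
        src, dst = routes[name]
        d[src] -= arr
        d[dst] += arr

    # oxygen slaved to the ledger
    resp_n = (fluxes["zoo_metab"] + fluxes["remin_sdet"] + fluxes["remin_ldet"]
              + fluxes["remin_pom"] + fluxes["remin_dom"] + fluxes["remin_oydet"])
    o2_prod = (params.o2_per_no3_uptake * fluxes["uptake_no3"]
               + params.o2_per_nh4_uptake * fluxes["uptake_nh4"])
    o2_resp = params.o2_per_n_resp * resp_n
    o2_nitr = params.o2_per_nh4_nitrif * fluxes["nitrif"]
    d["o2"] = o2_prod - o2_resp - o2_nitr

    # phosphate slaved at fixed N:P
    d["po4"] = (resp_n - uptake) / params.r_np

    # chlorophyll: acclimated synthesis, losses proportional to phy losses
    # (phy below 1e-12 is treated as empty so the ratio stays finite)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(phy > 1e-12,
                         state["chl"] / np.where(phy > 1e-12, phy, 1.0), 0.0)
    phy_loss = graz + fluxes["phy_mort"] + agg_phy
    d["chl"] = chl_acclimation(phy, state["chl"], mu, I, params) - theta * phy_loss

    return RateTendencies(d=d, fluxes=fluxes, o2_production=o2_prod,
                          o2_respiration=o2_resp, o2_nitrification=o2_nitr,
                          light=I)


_FLUX_ROUTES = {
    "uptake_no3": ("no3", "phy"),
    "uptake_nh4": ("nh4", "phy"),
    "graz_to_zoo": ("phy", "zoo"),
    "graz_egest": ("phy", "sdet"),
    "phy_mort": ("phy", "sdet"),
    "zoo_metab": ("zoo", "nh4"),
    "zoo_mort": ("zoo", "sdet"),
    "agg_phy": ("phy", "ldet"),
    "agg_sdet": ("sdet", "ldet"),
    "remin_sdet": ("sdet", "nh4"),
    "remin_ldet": ("ldet", "nh4"),
    "remin_pom": ("pom_t", "nh4"),
    "remin_dom": ("dom_t", "nh4"),
    "remin_oydet": ("oydet", "nh4"),
    "nitrif": ("nh4", "no3"),
}
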