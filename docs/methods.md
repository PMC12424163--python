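# Methods

`hypoxsim` couples a pelagic nitrogen–phosphorus–oxygen cycle, a
filter-feeding oyster farm, an instantly remineralizing sediment, and
prescribed one-dimensional column physics into a seasonal, ensemble-of-
columns simulator of coastal hypoxia.  This note records the model
formulation, the reasoning behind the open design choices, the numerical
treatment, what the synthetic data do and do not emulate, and the known
limitations.

## Pelagic biogeochemistry

The kernel tracks eleven pelagic state variables — nitrate, ammonium,
phosphate, oxygen, chlorophyll, phytoplankton, zooplankton, small and
large detritus, and river-delivered terrestrial particulate and dissolved
organic matter — plus a twelfth pool of oyster-derived detritus that is
identically zero without a farm.  Functional forms follow the conventions
of the Fennel family of coastal nitrogen-cycle models; the governing
coefficients are package defaults (a versioned `BGCParams` dataclass,
YAML-serializable), chosen at field-typical magnitudes, since no single
published coefficient set defines this configuration.

Growth is μ = μ_max(T)·f(I)·min(L_NO₃+L_NH₄, L_PO₄) with
μ_max = μ₀·1.066^T (μ₀ = 0.69 d⁻¹), f(I) = αI/√(μ_max²+α²I²)
(α = 0.025 (W m⁻²)⁻¹ d⁻¹), ammonium inhibition of nitrate uptake
L_NO₃ = [NO₃/(k_N+NO₃)]·[1/(1+NH₄/k_A)], and colimitation through the
minimum of the N and P terms (a multiplicative variant was considered and
rejected: the minimum keeps the realized limiting factor identifiable in
diagnostics).  The realized uptake is split between nitrate and ammonium
in proportion to their limitation terms.  Light decays with depth under
water and chlorophyll shading (k_d = 0.15 m⁻¹ + 0.025 m² (mg Chl)⁻¹).

Chlorophyll follows Geider-type photoacclimation: the fraction of
photosynthesis directed to pigment is ρ = θ_max·μ·Phy/(α·I·Chl) clamped to
[0, 1] (θ_max = 4.2 mg Chl (mmol N)⁻¹), with synthesis ρ·μ·Chl and losses
proportional to phytoplankton losses at the ambient ratio.  Two
consequences are deliberate and tested: at I = 0 the acclimation term is
defined as zero, and the Chl:Phy ratio relaxes to θ* = θ_max·μ/(αI) from
above only — chlorophyll-deficient cells grow at balanced rate under the
ρ ≤ 1 clamp.  At equilibrium the ratio sits exactly at its fixed point,
which makes chlorophyll neutrally determined in steady-state analyses (the
chemostat oracle test therefore compares the other state variables).

Grazing is Holling type III, g_max·Phy²/(k_P²+Phy²)·Zoo, with an
assimilated fraction β = 0.75 to zooplankton and the egested remainder to
small detritus.  Linear rates cover phytoplankton mortality, zooplankton
basal metabolism (to ammonium, with oxygen cost) and remineralization of
the four detrital/terrestrial pools; zooplankton also suffer quadratic
mortality, routed to small detritus (the large-detritus alternative is a
one-line change; small detritus was chosen because copepod carcasses and
fecal fragments are predominantly slow-sinking).  Aggregation transfers
τ(Phy+SDet)² into large detritus, removed from the two sources in
proportion to their share.  Nitrification is n_max·NH₄·Φ(I) with the
threshold/saturation inhibition Φ(I) = 1 − max(0, I−I₀)/(k_I + I−I₀): one
in the dark, half-inhibited at I = I₀+k_I, vanishing under strong light.
This smooth form was preferred over a piecewise-linear stand-in because it
has the same contract (Φ(0)=1, monotone, →0) and an exact half-inhibition
point for testing.

Stoichiometry: organic matter carries N:P = 16; phosphate is consumed and
regenerated by every nitrogen flux at that ratio.  Oxygen is produced at
8.625 mol O₂ per mol N of nitrate-fuelled and 6.625 of ammonium-fuelled
photosynthesis, consumed at 6.625 by respiration/remineralization and 2 by
nitrification.  Oxygen units are mmol/m³ throughout; thresholds given in
mg/L convert at 1 mg/L = 31.25 mmol/m³ (molar mass 32 g/mol).

Nitrogen is conserved *structurally*: the kernel emits a named ledger of
transfers (uptake, grazing, mortality, aggregation, remineralization,
nitrification), each debiting one pool and crediting another; tendencies
are assembled from the ledger, and phosphate and oxygen are slaved to it.
Oxygen-consuming rates scale by the piecewise-linear throttle
min(1, O₂/O₂_lim) with O₂_lim = 10 mmol/m³.  The clip form (rather than a
Michaelis–Menten factor) is deliberate: it is exactly one at ample oxygen,
so time-integrated stoichiometric budgets close to round-off, while still
driving consumption to zero before oxygen can go negative.  A final safety
clamp exists in the integrator but is booked in the oxygen ledger so
closure checks would expose it if it ever carried real weight.

## Oyster module

The farm holds a fixed biomass of 1 g dry weight per individual
(0.07 g N/g DW), at 100 individuals/m² over 100 km² in the default Oyster
scenario, occupying the upper ~4 m of its column.  Filtration clears water
at 0.08 m³ ind⁻¹ d⁻¹ scaled by trapezoidal temperature (5–18–30–38 °C) and
salinity (2–10–35–40 PSU) responses and an oxygen ramp that shuts the
animals down entirely below 31.25 mmol/m³ (~1 mg/L).  The same specific
clearance rate applies to all five food pools (phytoplankton, zooplankton,
both detritus classes, terrestrial POM), capped so no more than 90 % of
the standing stock can be removed in one step.  Of the filtered stream,
5 % is rejected as pseudofeces; ingested matter is assimilated at
food-specific efficiencies (0.8 living, 0.5 detrital, 0.3 terrestrial),
the rest egested.  Pseudofeces, feces and mortality feed the
oyster-detritus pool, which sinks at 5 m/d and remineralizes at 0.2 d⁻¹ in
the water column and instantly in the sediment.

Metabolism catabolizes half of assimilated nitrogen to ammonium (phosphate
at N:P), plus a basal term of 0.001 d⁻¹ of stock nitrogen with Q10 = 2,
with oxygen cost (basal + 0.1 × assimilated) × 6.625.  Mortality returns
0.001 d⁻¹ of stock nitrogen.  Because biomass is fixed (no growth or
harvest is simulated), assimilated nitrogen not returned by excretion or
mortality is booked as removed from the modelled system — the accounting
that defines the net-removal budget.  The basal/mortality/excretion
defaults were set so that returns are dominated by the assimilation-
proportional term and net removal stays a positive ~20–30 % of
assimilation, the regime reported for commercial-scale farms; with the
earlier, larger stock-based defaults a food-limited column farm went net
negative, which is not how real farms operate.

## Sediment

All oceanic sinking organic matter (phytoplankton, detritus, oyster
detritus) reaching the bed is processed the same step; terrestrial POM is
processed at 50 %, the remainder buried.  A denitrified fraction
f_denit = 0.25 of processed nitrogen leaves as N₂ with no bottom-water
oxygen cost (anaerobic pathway); the rest returns as ammonium with its
full aerobic cost of 6.625 mol O₂ per mol N, throttled by the bottom-water
oxygen clip and additionally capped at the oxygen actually present.
Phosphorus of processed matter returns completely; buried terrestrial POM
takes its phosphorus with it.  Benthic nitrogen closure
(deposit = NH₄ + N₂ + burial) is exact by construction.  Benthic
nitrification of the returned ammonium before release is excluded; the
water-column nitrification pathway handles it one step later.

## Column physics

The three-dimensional circulation of an estuary–shelf system cannot be
desk-scaled, so physics is prescribed rather than prognostic — the design
lever is stratification, which is what the scenario analysis manipulates.
Temperature and salinity profiles blend surface forcing values to
climatological bottom values (22 °C, 34 PSU) across a tanh pycnocline at
35 % of column depth; surface salinity follows the river plume through a
linear discharge map, and 30 % of the surface warming anomaly reaches the
bottom.  N² comes from a linear equation of state
(α_T = 2.5 × 10⁻⁴ K⁻¹, β_S = 7.6 × 10⁻⁴ PSU⁻¹); unstable (negative) N² is
mapped to the strong-mixing limit.  Vertical diffusivity is the surrogate
K = K_bg + K₀/(1 + N²/N₀²) with K_bg = 5 × 10⁻⁶ m²/s, K₀ = 2 × 10⁻³ m²/s,
N₀² = 2 × 10⁻⁵ s⁻², strictly decreasing in N² and floored at K_bg.  No
quantitative K–N² relation is claimed by the source literature this
emulates; these constants were tuned once so the default fixture develops
seasonal bottom hypoxia of plausible extent, and a `strat_multiplier`
exposes the N²-scaling used by the mechanism tests.  A small hypsography
(by default a 100 km² farm-footprint column plus deeper shelf columns
totalling 3000 km²) represents the regional volume so hypoxic volume can
be diagnosed without a 3-D grid.

Because a single column has no lateral exchange, river inputs would
accumulate without bound; a flushing term relaxes every tracer except
oxygen toward offshore background concentrations at 0.03 d⁻¹ (a ~30-day
residence time, realistic for a river-plume shelf).  Oxygen is excluded so
the bottom-water oxygen budget remains a closed ledger of diffusion and
local sources/sinks; the flushing flux is booked in the nitrogen ledger,
and conservation tests run with flushing off.

River loads enter the surface layer as discharge × concentration spread
over the regional area; the load ledger records them.  Air–sea exchange
uses a quadratic wind-speed piston velocity (0.31 cm hr⁻¹ (m s⁻¹)⁻²,
Schmidt-number corrected) relaxing the surface layer toward the
Garcia–Gordon solubility.

## Numerics

One step applies, in order: biology + oyster tendencies (explicit Euler by
default; midpoint RK2 available), river input, flushing, sinking, sediment
processing, implicit vertical diffusion, then air–sea exchange.

* **Diffusion** is a conservative finite-volume θ-scheme solved
  tridiagonally (interface j sits between layers j−1 and j): backward
  Euler (θ = 1) in production for monotonicity at daily-scale steps;
  Crank–Nicolson (θ = ½) is available and is the path the
  matrix-exponential oracle test exercises, since a first-order scheme
  cannot meet a 10⁻⁸ comparison in one step.
* **Sinking** uses the spatially first-order upwind operator integrated
  *exactly* in time via a cached matrix exponential of its bidiagonal
  generator.  The more common substepped explicit form was implemented
  first and rejected: its numerical diffusion depends on the CFL number
  and therefore on dt, which made dt-refinement studies of the coupled
  model non-convergent.  The exact propagator is dt-consistent, needs no
  CFL constraint, and is exercised by conservation and kinematics tests.
* **Positivity** is enforced by per-source-pool proportional flux
  limiting (transfers are scaled jointly on both sides, preserving
  conservation), a matching phosphate limit on uptake, a demand cap in the
  oyster module and the sediment oxygen cap; the final oxygen clamp is
  ledgered.
* **Convergence**: the split step is first-order consistent (verified by
  short-horizon refinement against a fine-dt reference), and season-end
  integrated inventories move by < 1 % under dt halving at the default
  dt = 0.5 d.  Pointwise season-end profiles are *not* dt-robust at the
  1 % level: the stiff diffusion/biology coupling near the pycnocline
  carries a large first-order splitting constant, and the subsurface bloom
  position shifts with dt.  Tests therefore assert the convergence order
  and the inventory robustness, not pointwise agreement.
* The oxygen budget below each column's reference interface (default: top
  of the deepest third, standing in for "bottom water") closes exactly per
  step by construction, and the diagnostics module asserts closure at
  10⁻⁸ on every archived run.

## Synthetic forcing and scenarios

The forcing generator emulates, statistically, the inputs a downscaled
climate/watershed modelling chain would provide: monthly series over
2015–2100 of irradiance, surface water temperature (linear warming,
default 0.45 °C/decade, an SSP5-8.5-like rate), wind, river discharge
(compound trend, default +3 %/decade, with a strong wet-season cycle),
plume-driven surface salinity, and a seasonal multiplier for river
nutrient concentrations.  Interannual variability is AR(1) with Gaussian
innovations (lag-1 autocorrelation 0.5), clipped at physical bounds;
every channel is bitwise-reproducible from (config, seed).

Scenario rules: ConstantN freezes river concentrations at their 2015
reference levels; DecreasingN declines each species linearly at configured
rates (floored at zero), with phosphate leveling off at 1 mmol/m³ from
2024 onward; the Oyster case inherits the DecreasingN rules and adds the
farm.  The 2015 reference concentrations (e.g. 100 mmol/m³ nitrate) and
decline rates are configuration values chosen so end-of-century
DecreasingN levels are a small fraction of 2015 levels; they are not
published measurements.  River organic phosphorus is not tracked
separately — organic matter carries N:P = 16 implicitly.

Experiments use a time-slice strategy: only May 1 – September 30 of each
year is simulated, initialized from a scenario-specific climatological May
state produced by a seeded 30-day burn-in (one per column, reused across
years).  Summer statistics are June–September means; comparison intervals
are the 25th/75th percentiles of per-year values.  The full design
contemplates the 30-year windows 2016–2045 and 2071–2100; the standard
fixture used by the tests and the acceptance script runs three-year
windows (2016–2018, 2098–2100) on a four-column, 16-layer ensemble at
dt = 0.5 d — sizes chosen as a deliberately scaled experiment whose
directional conclusions (scenario ordering, oyster effects, stratification
mechanism) are the tested claims.  Magnitudes of percent changes depend on
ensemble size and tuning and are reported, not asserted.

What the synthetic world does *not* emulate: lateral advection and plume
dynamics, tides, wind-driven currents, spatial structure within the farm,
event-scale weather (typhoon mixing), carbonate chemistry, and oyster
growth/harvest.  Passing tests therefore demonstrate internal consistency
and mechanism direction under controlled conditions, not predictive skill
for any real estuary.

## Removal accounting

The valuation chain uses nitrogen molar mass 14.0 g/mol and 365-day years:
g N m⁻² yr⁻¹ = (mol N/d × 14 × 365)/area; national removal scales that
rate to a national farming area (2349 km² default); the load fraction
divides by a 3.1 × 10⁶ t/yr riverine nitrogen input; valuation prices at
32.3 USD/kg-N.  Every conversion is cross-checked against an independent
unit-factor oracle in the tests.

## Known limitations

* One-dimensional columns with parameterized flushing cannot represent
  export pathways that matter in real shelf systems; the oyster effect on
  sediment deposition is sensitive to how much filtered material would
  otherwise have left the footprint laterally.
* The fixed-biomass farm ignores growth-dependent filtration, size
  structure and harvest; net removal scales linearly with stocking
  assumptions.
* The K(N²) surrogate compresses all mixing physics into two constants;
  only the sign of its response to stratification is mechanistically
  defensible.
* Pointwise fields at the default dt carry O(5 %/day-of-transient)
  splitting error near sharp pycnoclines; budgets and inventories are the
  robust outputs.
* The hypoxia magnitudes of the standard fixture follow from the one-time
  tuning of the physics surrogate and river defaults; they are plausible,
  not calibrated to observations.
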