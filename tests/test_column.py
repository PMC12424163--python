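"""Column physics: stratification, mixing, transport, gas exchange, stepping."""

import numpy as np
import pytest
from scipy.linalg import expm

from hypoxsim.bgc import BGCParams, BGCState, TRACERS
from hypoxsim.column import (GRAVITY, ColumnGrid, ColumnModel, PhysicsParams,
                             airsea_o2, diffuse, diffusion_operator,
                             kz_from_n2, make_ts_profiles, n2_from_ts,
                             o2_saturation, run_column, sink)
from hypoxsim.sediment import SedimentParams


def abiotic_state(nz, o2=200.0):
    return BGCState.uniform(nz, no3=0, nh4=0, po4=0, chl=0, phy=0, zoo=0,
                            sdet=0, ldet=0, pom_t=0, dom_t=0, o2=o2)


def uniform_physics(**kw):
    """Physics with no pycnocline contrast so prescribed T/S are uniform."""
    base = dict(t_bottom=24.0, bottom_warming_frac=1.0, t_surf_ref=24.0,
                s_bottom=24.0)
    base.update(kw)
    return PhysicsParams(**base)


QUIET_FORCING = dict(temperature=24.0, salinity=24.0, irradiance=0.0,
                     wind=0.0, discharge=0.0)


class TestGrid:
    def test_regular_grid_sums_to_depth(self):
        g = ColumnGrid.regular(20.0, nz=30)
        assert g.nz == 30
        assert g.depth == pytest.approx(20.0)
        # boundary refinement: surface layer thinner than mid-column
        assert g.dz[0] < g.dz[g.nz // 2]

    def test_invalid_thickness_rejected(self):
        with pytest.raises(ValueError):
            ColumnGrid(dz=np.array([1.0, -0.5]))


class TestStratification:
    def test_uniform_water_has_zero_n2(self):
        g = ColumnGrid.regular(20.0, nz=10)
        p = PhysicsParams()
        n2 = n2_from_ts(np.full(10, 20.0), np.full(10, 30.0), g, p)
        np.testing.assert_allclose(n2, 0.0, atol=1e-14)

    def test_fresh_warm_over_salty_cold_is_stable(self):
        g = ColumnGrid(dz=np.array([5.0, 5.0]))
        p = PhysicsParams()
        n2 = n2_from_ts(np.array([28.0, 20.0]), np.array([15.0, 34.0]), g, p)
        assert n2[0] > 0.0

    def test_linear_density_profile_closed_form(self):
        # T decreasing linearly with depth at 1 degC/m gives a uniform
        # density slope s = rho0*alpha_t, hence N^2 = g*alpha_t
        g = ColumnGrid(dz=np.full(8, 2.0))
        p = PhysicsParams()
        T = 28.0 - 1.0 * g.z_centers
        n2 = n2_from_ts(T, np.full(8, 30.0), g, p)
        np.testing.assert_allclose(n2, GRAVITY * p.alpha_t, rtol=1e-12)

    def test_kz_law_endpoints_and_midpoint(self):
        p = PhysicsParams()
        assert kz_from_n2(np.array([0.0]), p)[0] == pytest.approx(p.k_bg + p.k0)
        assert kz_from_n2(np.array([1e9]), p)[0] == pytest.approx(p.k_bg, rel=1e-6)
        assert kz_from_n2(np.array([p.n0_sq]), p)[0] == pytest.approx(
            p.k_bg + p.k0 / 2.0)
        # negative (unstable) N^2 maps to the strong-mixing limit
        assert kz_from_n2(np.array([-1e-4]), p)[0] == pytest.approx(p.k_bg + p.k0)

    def test_negative_mixing_params_rejected(self):
        with pytest.raises(ValueError):
            kz_from_n2(np.array([0.0]), PhysicsParams(k0=-1.0))


class TestDiffusion:
    def test_uniform_profile_is_equilibrium(self):
        g = ColumnGrid.regular(10.0, nz=12)
        c = np.full(12, 3.7)
        out = diffuse(c, np.full(11, 1e-3), 1.0, g)
        np.testing.assert_allclose(out, 3.7, rtol=1e-14)

    def test_inventory_conserved(self):
        rng = np.random.default_rng(0)
        g = ColumnGrid.regular(15.0, nz=20)
        c = rng.uniform(0, 10, 20)
        kz = rng.uniform(1e-6, 1e-3, 19)
        out = diffuse(c, kz, 0.5, g)
        assert np.sum(out * g.dz) == pytest.approx(np.sum(c * g.dz), rel=1e-12)

    @pytest.mark.parametrize("nz,dzs", [(3, [1.0, 2.0, 1.5]),
                                        (5, [0.5, 1.0, 2.0, 1.0, 0.5])])
    def test_matches_matrix_exponential_oracle(self, nz, dzs):
        g = ColumnGrid(dz=np.array(dzs))
        kz = np.linspace(1e-4, 5e-5, nz - 1)
        c0 = np.zeros(nz)
        c0[0], c0[-1] = 1.0, 3.0
        dt = 0.25
        exact = expm(diffusion_operator(kz, g) * dt * 86400.0) @ c0
        approx = diffuse(c0, kz, dt, g, theta=0.5, substeps=4000)
        np.testing.assert_allclose(approx, exact, atol=1e-8)

    def test_invalid_dt_rejected(self):
        g = ColumnGrid.regular(10.0, nz=5)
        with pytest.raises(ValueError):
            diffuse(np.zeros(5), np.zeros(4), -1.0, g)


class TestSinking:
    def test_zero_speed_is_identity(self):
        g = ColumnGrid.regular(10.0, nz=8)
        c = np.arange(8.0)
        out, dep = sink(c, 0.0, 1.0, g)
        np.testing.assert_array_equal(out, c)
        assert dep == 0.0

    def test_inventory_plus_deposition_conserved(self):
        g = ColumnGrid.regular(20.0, nz=15)
        rng = np.random.default_rng(1)
        c = rng.uniform(0, 5, 15)
        inv0 = np.sum(c * g.dz)
        dep_total = 0.0
        for _ in range(40):
            c, dep = sink(c, 8.0, 0.5, g)
            dep_total += dep
        assert np.sum(c * g.dz) + dep_total == pytest.approx(inv0, rel=1e-12)

    def test_parcel_arrival_kinematics(self):
        # uniform grid: a surface parcel's centre of mass reaches the bottom
        # in about depth/speed days
        g = ColumnGrid(dz=np.full(20, 1.0))
        c = np.zeros(20)
        c[0] = 10.0
        speed, dt = 2.0, 0.1
        t, deposited = 0.0, 0.0
        while deposited < 5.0:    # half the inventory delivered
            c, dep = sink(c, speed, dt, g)
            deposited += dep
            t += dt
        assert t == pytest.approx(g.depth / speed, rel=0.15)

    def test_negative_speed_rejected(self):
        g = ColumnGrid.regular(10.0, nz=5)
        with pytest.raises(ValueError):
            sink(np.zeros(5), -1.0, 1.0, g)


class TestAirSea:
    def test_flux_zero_at_saturation(self):
        sat = float(o2_saturation(24.0, 30.0))
        new, flux = airsea_o2(sat, 24.0, 30.0, 6.0, 0.5, 1.0)
        assert flux == pytest.approx(0.0, abs=1e-10)
        assert new == pytest.approx(sat)

    def test_undersaturation_drives_invasion(self):
        _, flux = airsea_o2(100.0, 24.0, 30.0, 6.0, 0.5, 1.0)
        assert flux > 0.0

    def test_abiotic_column_relaxes_to_saturation(self):
        phys = uniform_physics()
        g = ColumnGrid.regular(10.0, nz=8)
        model = ColumnModel(g, physics=phys, flushing_rate=0.0)
        sat = float(o2_saturation(24.0, 24.0))
        state = abiotic_state(8, o2=0.5 * sat)
        for _ in range(400):
            model.step(state, QUIET_FORCING | {"wind": 7.0}, 0.5)
        assert state["o2"][0] == pytest.approx(sat, rel=1e-3)

    def test_solubility_decreases_with_warming_and_salt(self):
        assert o2_saturation(30.0, 30.0) < o2_saturation(20.0, 30.0)
        assert o2_saturation(24.0, 35.0) < o2_saturation(24.0, 5.0)


class TestCoupledStep:
    def test_all_zero_biology_uniform_column_is_fixed_point(self):
        phys = uniform_physics()
        g = ColumnGrid.regular(12.0, nz=10)
        model = ColumnModel(g, physics=phys, flushing_rate=0.0)
        sat = float(o2_saturation(24.0, 24.0))
        state = abiotic_state(10, o2=sat)
        before = state.copy()
        for _ in range(10):
            model.step(state, QUIET_FORCING, 0.5)
        for k in TRACERS:
            np.testing.assert_allclose(state[k], before[k], atol=1e-9)

    def test_oxygen_ledger_identity_every_step(self):
        g = ColumnGrid.regular(16.0, nz=12)
        model = ColumnModel(g)
        state = BGCState.uniform(12)
        f = dict(temperature=28.0, salinity=18.0, irradiance=180.0, wind=5.0,
                 discharge=12000.0, river_no3=60.0, river_nh4=5.0,
                 river_po4=1.5, river_don=12.0, river_pon=8.0)
        for _ in range(60):
            led = model.step(state, f, 0.5)
            rhs = (led["o2_diff_in"] + led["o2_prod_below"]
                   - led["o2_resp_below"] - led["o2_nitr_below"]
                   - led["o2_oyster_below"] - led["o2_sod"]
                   + led["o2_clamp_below"])
            assert led["o2_dinv_below"] == pytest.approx(rhs, abs=1e-9)

    def test_full_season_mass_conservation(self):
        # tracer mass (water column + sediment exports + river imports)
        # closes to 1e-10 relative over a full May-September season
        g = ColumnGrid.regular(16.0, nz=12)
        model = ColumnModel(g, flushing_rate=0.0)
        state = BGCState.uniform(12)
        n0 = state.total_nitrogen(g.dz)
        f = dict(temperature=28.0, salinity=18.0, irradiance=180.0, wind=5.0,
                 discharge=12000.0, river_no3=60.0, river_nh4=5.0,
                 river_po4=1.5, river_don=12.0, river_pon=8.0)
        run = run_column(model, state, [f] * 306, 0.5, archive_every=306)
        led = run.ledger
        n_end = state.total_nitrogen(g.dz)
        losses = led[["n_n2_loss", "n_burial", "n_oyster_removed"]].sum().sum()
        imports = led["n_river_in"].sum()
        assert n_end + losses - imports == pytest.approx(n0, rel=1e-10)

    def test_stratification_multiplier_suppresses_bottom_o2_supply(self):
        # scaling N^2 up monotonically decreases the diffusive oxygen flux
        # into the bottom of an abiotic column
        g = ColumnGrid.regular(16.0, nz=12)
        supplies = []
        for mult in (0.25, 1.0, 4.0, 16.0):
            model = ColumnModel(
                g, physics=PhysicsParams(strat_multiplier=mult),
                flushing_rate=0.0, reference_interface=g.nz - 1)
            state = abiotic_state(12)
            state["o2"][-1] = 20.0   # oxygen-poor bottom layer
            total = 0.0
            for _ in range(20):
                led = model.step(state, dict(temperature=29.0, salinity=15.0,
                                             irradiance=0.0, wind=5.0,
                                             discharge=0.0), 0.5)
                total += led["o2_diff_in"]
            supplies.append(total)
        assert all(a > b for a, b in zip(supplies, supplies[1:]))

    def test_dt_refinement_converges_at_first_order(self):
        # the operator-split step is first-order consistent: over a short
        # horizon the error against a fine-dt reference shrinks roughly in
        # proportion to dt
        g = ColumnGrid.regular(14.0, nz=10)
        f = dict(temperature=28.0, salinity=20.0, irradiance=160.0, wind=5.0,
                 discharge=9000.0, river_no3=50.0, river_nh4=4.0,
                 river_po4=1.2, river_don=10.0, river_pon=7.0)

        def run(dt, days=2.0):
            model = ColumnModel(g)
            state = BGCState.uniform(10)
            for _ in range(int(round(days / dt))):
                model.step(state, f, dt)
            return state

        ref = run(1.0 / 128.0)
        errs = []
        for dt in (0.25, 0.125, 0.0625):
            a = run(dt)
            errs.append(max(
                np.max(np.abs(a[k] - ref[k])) / max(np.max(np.abs(ref[k])), 1.0)
                for k in ("o2", "no3", "phy")))
        ratios = [b / a for a, b in zip(errs, errs[1:])]
        assert all(r < 0.85 for r in ratios)      # shrinking at every halving
        assert errs[-1] < errs[0] / 2.0           # net reduction ~first order

    def test_dt_halving_season_inventory_within_one_percent(self):
        # integrated quantities (the budgets the diagnostics consume) are
        # dt-robust: total nitrogen inventory at season end moves by <1%
        # when the step is halved
        g = ColumnGrid.regular(14.0, nz=10)
        f = dict(temperature=27.0, salinity=22.0, irradiance=150.0, wind=6.0,
                 discharge=6000.0, river_no3=30.0, river_nh4=3.0,
                 river_po4=1.0, river_don=8.0, river_pon=5.0)
        totals = {}
        for dt in (0.5, 0.25):
            model = ColumnModel(g)
            state = BGCState.uniform(10)
            for _ in range(int(153 / dt)):
                model.step(state, f, dt)
            totals[dt] = state.total_nitrogen(g.dz)
        assert abs(totals[0.5] - totals[0.25]) / totals[0.25] < 0.01

    def test_occupied_layers_outside_grid_rejected(self):
        from hypoxsim.oyster import OysterPopulation
        g = ColumnGrid.regular(10.0, nz=5)
        with pytest.raises(ValueError):
            ColumnModel(g, population=OysterPopulation(occupied_layers=(0, 7)))

    def test_oyster_biodeposit_pulse_o2_stoichiometry(self):
        # a pulse of oyster detritus in a closed dark column draws down
        # exactly pulse N x O2:N, whether remineralized in the water column
        # or in the sediment (denitrification off, ample oxygen)
        g = ColumnGrid.regular(10.0, nz=6)
        bgc = BGCParams(n_max=0.0)
        model = ColumnModel(g, bgc_params=bgc,
                            sediment=SedimentParams(f_denit=0.0,
                                                    pom_remin_frac=1.0),
                            physics=uniform_physics(piston_coef=0.0),
                            flushing_rate=0.0)
        state = abiotic_state(6, o2=1000.0)
        state["oydet"] = np.full(6, 0.5)
        pulse = state.total_nitrogen(g.dz)      # all N is oyster detritus
        inv0 = float(np.sum(state["o2"] * g.dz))
        for _ in range(400):
            model.step(state, QUIET_FORCING, 0.25)
        assert float(np.sum(state["oydet"] * g.dz)) < 1e-8 * pulse
        drawdown = inv0 - float(np.sum(state["o2"] * g.dz))
        assert drawdown == pytest.approx(pulse * bgc.o2_per_n_resp, rel=1e-6)
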